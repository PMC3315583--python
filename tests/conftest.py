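import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study shared by read-level tests."""
    from estforge import simulate

    cfg = simulate.SimConfig(seed=42, n_genes=20, n_reads=400,
                             transcript_len_range=(400, 1200))
    return simulate.simulate_dataset(cfg, n_chroms=2, spacer_len=300)
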