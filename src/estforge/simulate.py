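"""Synthetic transcriptome, reference genome and 454-like read generator.

The generator emulates the statistical structure a 454 EST experiment on a
polyploid grass presents to the downstream pipeline:

* a toy transcriptome containing singleton genes plus paralog *families*
  derived from a common ancestor by point substitution (a proxy for
  polyploid homeologs), optionally with an identical conserved block shared
  by all family members;
* embedded perfect microsatellites and retroelement fragments with recorded
  ground-truth coordinates;
* normalized cDNA libraries: per-library log-normal abundances flattened by
  a power law ``w**gamma`` (gamma <= 1) before renormalization;
* long single-end reads with a left-skewed length distribution
  (mean ~367 bp, median ~395 bp, hard maximum 695 bp), ~99.5% per-base
  accuracy split between substitutions and homopolymer-length indels whose
  probability grows with run length, plus optional 5' adapter and poly-A/T
  contamination.

Everything is deterministic given the configured seed; the library label is
folded into the seed stream so each library is individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special

from .seqio import Read, SSRLocus
from .align import revcomp

BASES = np.array(list("ACGT"))

_DEF_ADAPTER = "GCCTCCCTCGCGCCATCAG"  # 454 Titanium primer A


class SimConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the toolkit's study conditions."""

    seed: int = 0
    n_genes: int = 60
    paralog_family_prob: float = 0.15
    family_size_range: tuple = (2, 4)
    paralog_divergence: float = 0.05   # expected *pairwise* substitution fraction
    conserved_block_len: int = 0       # identical block shared by family members
    ssr_insert_prob: float = 0.2
    ssr_unit_len_range: tuple = (2, 6)
    ssr_unit_count_range: tuple = (8, 12)
    retro_family_count: int = 4
    retro_len_range: tuple = (300, 600)
    retro_insert_prob: float = 0.1
    retro_fragment_range: tuple = (150, 400)
    transcript_len_range: tuple = (300, 2000)
    n_reads: int = 2000                # per library
    read_len_mean: float = 367.0
    read_len_max: int = 695
    read_len_min: int = 50
    read_len_shape: float = 3.8        # gamma shape of the reflected length model
    per_base_accuracy: float = 0.995
    adapters: tuple = (_DEF_ADAPTER,)
    adapter_prob: float = 0.5
    polyA_prob: float = 0.5
    polyA_len_range: tuple = (8, 25)
    normalization_gamma: float = 0.3
    libraries: tuple = ("seed", "seedling", "tiller", "flower")

    def __post_init__(self) -> None:
        for name in ("paralog_family_prob", "ssr_insert_prob", "retro_insert_prob",
                     "adapter_prob", "polyA_prob", "per_base_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.normalization_gamma <= 1.0:
            raise SimConfigError("normalization_gamma must be in (0,1]")
        for name in ("family_size_range", "ssr_unit_len_range", "ssr_unit_count_range",
                     "transcript_len_range", "retro_len_range", "retro_fragment_range",
                     "polyA_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SimConfigError(f"{name} is empty or negative: ({lo},{hi})")
        max_ssr = self.ssr_unit_len_range[1] * self.ssr_unit_count_range[1]
        if self.ssr_insert_prob > 0 and max_ssr >= self.transcript_len_range[0]:
            raise SimConfigError("largest SSR insert does not fit the shortest transcript")
        if self.seed < 0:
            raise SimConfigError("seed must be non-negative")


@dataclass
class Provenance:
    """Where one simulated read came from."""

    transcript: str
    start: int
    end: int            # half-open on the transcript, before errors
    strand: str
    n_subst: int
    n_indel: int


@dataclass
class Truth:
    """Ground truth for one simulated dataset."""

    transcripts: dict = field(default_factory=dict)
    families: list = field(default_factory=list)           # [[tid, ...], ...]
    divergent_sites: dict = field(default_factory=dict)    # family idx -> sorted positions
    ssr_loci: list = field(default_factory=list)           # [SSRLocus]
    retro_intervals: list = field(default_factory=list)    # [(tid, start, end, family_id)]
    retro_db: dict = field(default_factory=dict)           # family_id -> sequence
    abundances: dict = field(default_factory=dict)         # library -> np.ndarray
    provenance: dict = field(default_factory=dict)         # read id -> Provenance
    reference_loci: dict = field(default_factory=dict)     # tid -> (chrom, start, end, strand)


def _lib_rng(seed: int, library: str, salt: int = 0) -> np.random.Generator:
    # fold the library label into the seed stream; each library reproducible alone
    return np.random.default_rng([seed, zlib.crc32(library.encode()) & 0x7FFFFFFF, salt])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protect: Optional[range] = None) -> tuple:
    """Substitute each base independently with probability ``rate``.

    Returns (mutated sequence, list of mutated positions)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < rate
    if protect is not None:
        hit[protect.start:protect.stop] = False
    positions = np.flatnonzero(hit)
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr), positions.tolist()


def _primitive_unit(rng: np.random.Generator, ul: int) -> str:
    """A repeat unit that is not itself a tandem of a shorter unit."""
    while True:
        unit = _random_dna(rng, ul)
        if all(unit != unit[:p] * (ul // p) for p in range(1, ul) if ul % p == 0):
            return unit


def make_transcriptome(config: SimConfig) -> tuple:
    """Generate transcripts (singletons + paralog families) with ground truth.

    SSRs and retroelement fragments are embedded per-transcript with the
    configured probabilities; embedded SSR flanks are guarded so the planted
    locus is maximal exactly as recorded.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = Truth()
    retro_rng = np.random.default_rng([config.seed, 2])
    for i in range(config.retro_family_count):
        L = int(retro_rng.integers(config.retro_len_range[0], config.retro_len_range[1] + 1))
        truth.retro_db[f"retro{i:02d}"] = _random_dna(retro_rng, L)

    gene = 0
    while gene < config.n_genes:
        L = int(rng.integers(config.transcript_len_range[0], config.transcript_len_range[1] + 1))
        ancestor = _random_dna(rng, L)
        in_family = rng.random() < config.paralog_family_prob
        if in_family:
            size = int(rng.integers(config.family_size_range[0], config.family_size_range[1] + 1))
            block = None
            if config.conserved_block_len and config.conserved_block_len < L:
                b0 = (L - config.conserved_block_len) // 2
                block = range(b0, b0 + config.conserved_block_len)
            members, site_sets = [], []
            for m in range(size):
                seq, sites = _mutate(ancestor, config.paralog_divergence / 2.0, rng, protect=block)
                tid = f"g{gene:04d}{chr(ord('a') + m)}"
                members.append(tid)
                site_sets.append(set(sites))
                truth.transcripts[tid] = seq
            truth.families.append(members)
            truth.divergent_sites[len(truth.families) - 1] = sorted(set().union(*site_sets))
        else:
            truth.transcripts[f"g{gene:04d}"] = ancestor
        gene += 1

    # embed SSRs and retro fragments (insertion, coordinates recorded)
    for tid in list(truth.transcripts):
        seq = truth.transcripts[tid]
        if rng.random() < config.ssr_insert_prob:
            ul = int(rng.integers(config.ssr_unit_len_range[0], config.ssr_unit_len_range[1] + 1))
            uc = int(rng.integers(config.ssr_unit_count_range[0], config.ssr_unit_count_range[1] + 1))
            unit = _primitive_unit(rng, ul)
            pos = int(rng.integers(1, len(seq) - 1))
            repeat = unit * uc
            left, right = seq[:pos], seq[pos:]
            # guard flanks so the planted locus stays maximal at the recorded span
            if left and left[-1] == unit[-1]:
                left = left[:-1] + ("C" if unit[-1] != "C" else "G")
            if right and right[0] == unit[0]:
                right = ("C" if unit[0] != "C" else "G") + right[1:]
            seq = left + repeat + right
            from .ssr import canonical_motif
            truth.ssr_loci.append(SSRLocus(
                seq_id=tid, start=len(left), end=len(left) + ul * uc,
                motif=unit, canonical=canonical_motif(unit), unit_len=ul, unit_count=uc))
        if truth.retro_db and rng.random() < config.retro_insert_prob:
            fam = sorted(truth.retro_db)[int(rng.integers(0, len(truth.retro_db)))]
            rseq = truth.retro_db[fam]
            flen = int(rng.integers(config.retro_fragment_range[0],
                                    min(config.retro_fragment_range[1], len(rseq)) + 1))
            rstart = int(rng.integers(0, len(rseq) - flen + 1))
            frag = rseq[rstart:rstart + flen]
            pos = int(rng.integers(0, len(seq) + 1))
            seq = seq[:pos] + frag + seq[pos:]
            truth.retro_intervals.append((tid, pos, pos + flen, fam))
        truth.transcripts[tid] = seq

    if not truth.transcripts:
        raise SimConfigError("n_genes produced no transcripts")
    return truth.transcripts, truth


def make_reference(transcripts: Mapping[str, str], n_chroms: int = 2,
                   spacer_len: int = 300, seed: int = 0) -> tuple:
    """Place transcripts on chromosomes with random strand and fixed spacers.

    Each chromosome is spacer-flanked: ``spacer t spacer t ... spacer``, so a
    chromosome carrying n transcripts has length sum(len) + (n+1)*spacer_len.
    Returns ``(genome, loci)`` with loci ``tid -> (chrom, start, end, strand)``.
    """
    if n_chroms < 1:
        raise SimConfigError("n_chroms must be >= 1")
    rng = np.random.default_rng([seed, 3])
    tids = list(transcripts)
    order = [tids[i] for i in rng.permutation(len(tids))]
    per_chrom = [order[c::n_chroms] for c in range(n_chroms)]
    genome, loci = {}, {}
    for c, chrom_tids in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        parts = [_random_dna(rng, spacer_len)]
        pos = spacer_len
        for tid in chrom_tids:
            strand = "+" if rng.random() < 0.5 else "-"
            tseq = transcripts[tid]
            placed = tseq if strand == "+" else revcomp(tseq)
            parts.append(placed)
            loci[tid] = (chrom, pos, pos + len(tseq), strand)
            pos += len(tseq)
            parts.append(_random_dna(rng, spacer_len))
            pos += spacer_len
        genome[chrom] = "".join(parts)
    return genome, loci


def sample_abundances(config: SimConfig, library: str,
                      n: Optional[int] = None) -> np.ndarray:
    """Normalized-library transcript weights: lognormal draws flattened as w**gamma."""
    rng = _lib_rng(config.seed, library, salt=10)
    n = n if n is not None else config.n_genes
    raw = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    flat = raw ** config.normalization_gamma
    return flat / flat.sum()


def _calibrated_scale(config: SimConfig) -> float:
    """Gamma scale such that the reflected, truncated length model hits the mean."""
    k = config.read_len_shape
    U = config.read_len_max - config.read_len_min
    target = config.read_len_max - config.read_len_mean

    def trunc_mean(theta):
        x = U / theta
        return k * theta * special.gammainc(k + 1, x) / special.gammainc(k, x)

    return float(optimize.brentq(lambda t: trunc_mean(t) - target, 1.0, 400.0))


def draw_read_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Left-skewed lengths: read_len_max minus a truncated Gamma draw."""
    theta = _calibrated_scale(config)
    U = config.read_len_max - config.read_len_min
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        g = rng.gamma(config.read_len_shape, theta, size=2 * (n - filled))
        g = g[g <= U][: n - filled]
        out[filled:filled + len(g)] = np.round(config.read_len_max - g).astype(np.int64)
        filled += len(g)
    return out


def _error_rates(config: SimConfig) -> tuple:
    """Split the configured error budget between substitutions and homopolymer indels.

    Homopolymer indels get 40% of the budget; on random DNA the expected
    per-base indel rate is c * P(s[i]==s[i-1]) = c/4, which fixes c.
    """
    err = 1.0 - config.per_base_accuracy
    sub_rate = 0.6 * err
    indel_c = 0.4 * err / 0.25
    return sub_rate, indel_c


def _apply_454_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> tuple:
    """Substitutions + homopolymer-length +-1 indels, p_indel(run) = c*(run-1)."""
    sub_rate, indel_c = _error_rates(config)
    # homopolymer pass on the clean read
    out = []
    n_indel = 0
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = j - i
        out.append(seq[i:j])
        p = min(0.9, indel_c * (run - 1))
        if run >= 2 and rng.random() < p:
            n_indel += 1
            if rng.random() < 0.5:
                out[-1] = seq[i] * (run + 1)
            else:
                out[-1] = seq[i] * (run - 1)
        i = j
    mutated = "".join(out)
    mutated, subs = _mutate(mutated, sub_rate, rng)
    return mutated, len(subs), n_indel


def make_reads(transcripts: Mapping[str, str], weights: Sequence[float],
               config: SimConfig, library: str) -> tuple:
    """Simulate one library of 454-like reads with full provenance.

    ``weights`` are molar transcript abundances; the chance a read comes
    from a transcript is proportional to ``weight x length`` because cDNA
    nebulization yields fragments (hence reads) in proportion to molecule
    length.  Reads take a random strand, lengths from the left-skewed model
    truncated at the transcript length, then sequencing errors, an optional
    5' adapter and an optional terminal poly-A (forward) / poly-T (reverse)
    tract.
    """
    tids = list(transcripts)
    if not tids:
        raise SimConfigError("empty transcript set")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(tids):
        raise SimConfigError("weights length != transcript count")
    if not np.isclose(weights.sum(), 1.0):
        raise SimConfigError("weights must sum to 1")
    rng = _lib_rng(config.seed, library, salt=20)
    lens = np.array([len(transcripts[t]) for t in tids], dtype=float)
    pick_p = weights * lens
    pick_p /= pick_p.sum()
    picks = rng.choice(len(tids), size=config.n_reads, p=pick_p)
    lengths = draw_read_lengths(config, config.n_reads, rng)
    reads, prov = [], {}
    for i in range(config.n_reads):
        tid = tids[picks[i]]
        tseq = transcripts[tid]
        L = int(min(lengths[i], len(tseq)))
        start = int(rng.integers(0, len(tseq) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = tseq[start:start + L]
        if strand == "-":
            frag = revcomp(frag)
        if config.per_base_accuracy < 1.0:
            frag, n_sub, n_ind = _apply_454_errors(frag, config, rng)
        else:
            n_sub = n_ind = 0
        if config.adapters and rng.random() < config.adapter_prob:
            frag = config.adapters[int(rng.integers(0, len(config.adapters)))] + frag
        if rng.random() < config.polyA_prob:
            tail = int(rng.integers(config.polyA_len_range[0], config.polyA_len_range[1] + 1))
            if strand == "+":
                frag = frag + "A" * tail
            else:
                frag = "T" * tail + frag
        rid = f"{library}_{i:06d}"
        reads.append(Read(id=rid, seq=frag, library=library))
        prov[rid] = Provenance(transcript=tid, start=start, end=start + L,
                               strand=strand, n_subst=n_sub, n_indel=n_ind)
    return reads, prov


@dataclass
class SimDataset:
    """A complete simulated study: transcriptome, genome, reads, truth."""

    config: SimConfig
    transcripts: dict
    genome: dict
    reads: dict          # library -> [Read]
    truth: Truth


def simulate_dataset(config: SimConfig, n_chroms: int = 2,
                     spacer_len: int = 300) -> SimDataset:
    """Run the whole generator: transcriptome, reference, one read set per library."""
    transcripts, truth = make_transcriptome(config)
    genome, loci = make_reference(transcripts, n_chroms=n_chroms,
                                  spacer_len=spacer_len, seed=config.seed)
    truth.reference_loci = loci
    reads = {}
    for lib in config.libraries:
        w = sample_abundances(config, lib, n=len(transcripts))
        lib_reads, prov = make_reads(transcripts, w, config, lib)
        reads[lib] = lib_reads
        truth.abundances[lib] = w
        truth.provenance.update(prov)
    return SimDataset(config=config, transcripts=transcripts, genome=genome,
                      reads=reads, truth=truth)
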