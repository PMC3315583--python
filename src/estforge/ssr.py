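"""Perfect microsatellite (SSR) mining and summaries.

Only *perfect* tandem repeats are reported: a locus spans whole repeat
units, ends at the last full unit, and is maximal (not extendable by one
more full unit on either side).  Unit lengths run 2-6 with class-specific
minimum unit counts (di 8, tri 6, tetra 4, penta 3, hexa 3) and a 15-bp
minimum total length; both floors are read as ">=", which makes the two
rules mutually consistent (di >= 8 units is 16 bp >= 15; penta >= 3 units
is exactly 15 bp).  A repeat whose unit is itself a tandem of a shorter
unit (e.g. ATAT) is reported only at the shortest unit, so homopolymer runs
are never reported and no span is double-counted.

Motifs are normalized to a canonical form: the lexicographically smallest
string among all rotations of the motif and of its reverse complement
(AG/GA/TC/CT all become AG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .align import revcomp
from .seqio import SSRLocus

_ACGT = set("ACGT")


@dataclass
class SSRParams:
    unit_len_range: tuple = (2, 6)
    min_total_len: int = 15
    min_units: dict = field(default_factory=lambda: {2: 8, 3: 6, 4: 4, 5: 3, 6: 3})
    perfect_only: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.unit_len_range
        missing = [u for u in range(lo, hi + 1) if u not in self.min_units]
        if missing:
            raise ValueError(f"min_units missing unit lengths {missing}")


def canonical_motif(motif: str) -> str:
    """Smallest string over all rotations of the motif and of its reverse complement."""
    motif = motif.upper()
    if not set(motif) <= _ACGT:
        raise ValueError(f"non-DNA motif {motif!r}")
    rc = revcomp(motif)
    n = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a tandem of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def find_perfect_ssrs(seq: str, params: SSRParams = SSRParams(),
                      seq_id: str = "seq") -> list:
    """All maximal qualifying perfect tandem repeats in ``seq``, sorted by start.

    ``N`` never matches anything, so repeats cannot run through an N.
    """
    s = seq.upper()
    n = len(s)
    lo, hi = params.unit_len_range
    loci = []
    for ul in range(lo, min(hi, n - 1) + 1):
        i = 0
        while i < n - ul:
            if s[i] in _ACGT and s[i] == s[i + ul]:
                start = i
                while i < n - ul and s[i] in _ACGT and s[i] == s[i + ul]:
                    i += 1
                span = (i - start) + ul          # maximal periodic stretch incl. partial unit
                unit_count = span // ul
                total = ul * unit_count
                if (unit_count >= params.min_units[ul]
                        and total >= params.min_total_len):
                    unit = s[start:start + ul]
                    if _is_primitive(unit):
                        loci.append(SSRLocus(
                            seq_id=seq_id, start=start, end=start + total,
                            motif=unit, canonical=canonical_motif(unit),
                            unit_len=ul, unit_count=unit_count))
            else:
                i += 1
    loci.sort(key=lambda L: (L.start, L.unit_len))
    return loci


def find_ssrs_in_collection(seqs: Mapping[str, str],
                            params: SSRParams = SSRParams()) -> list:
    loci = []
    for sid in seqs:
        loci.extend(find_perfect_ssrs(seqs[sid], params, seq_id=sid))
    return loci


def summarize_ssrs(loci: Iterable[SSRLocus]) -> dict:
    """Summary tables: per unit-length class, per canonical motif, and
    a frequency-by-unit-count matrix, plus the count of distinct sequences
    containing at least one locus."""
    loci = list(loci)
    if not loci:
        empty = pd.DataFrame()
        return {"by_unit_len": empty, "by_motif": empty,
                "n_sequences_with_ssr": 0, "freq_by_unit_count": empty}
    df = pd.DataFrame([{
        "seq_id": L.seq_id, "unit_len": L.unit_len, "canonical": L.canonical,
        "unit_count": L.unit_count,
    } for L in loci])
    total = len(df)
    by_len = (df.groupby("unit_len").size().rename("count").to_frame())
    by_len["percent"] = (100.0 * by_len["count"] / total).round(1)
    by_motif = (df.groupby("canonical").size().rename("count").to_frame()
                .sort_values(["count", "canonical"], ascending=[False, True]))
    freq = (df.groupby(["unit_len", "unit_count"]).size().unstack(fill_value=0))
    return {
        "by_unit_len": by_len,
        "by_motif": by_motif,
        "n_sequences_with_ssr": int(df["seq_id"].nunique()),
        "freq_by_unit_count": freq,
    }
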