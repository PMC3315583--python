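"""Read cleaning: adapter removal, poly-A/T trimming, length and contaminant filters.

Trimming order is adapters first, then poly-A/T, then the length filter
(adapters flank the tails in library construction).  The minimum-length rule
is strict: reads shorter than ``min_len`` *after all trimming* are removed,
a read of exactly ``min_len`` is kept.  Every run balances exactly:
raw = kept + removed_short + removed_contaminant + removed_empty.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from . import align
from .seqio import CleanReport, Read


@dataclass
class CleanConfig:
    adapters: tuple = ()
    max_mismatch_frac: float = 0.1
    min_adapter_match: int = 8
    min_tail: int = 8
    min_len: int = 100
    contaminant_min_identity: float = 0.9
    contaminant_min_cov: float = 0.8
    contaminant_index_k: int = 12


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _adapter_bounds(seq: str, adapters, max_mismatch_frac: float, min_match: int) -> tuple:
    """(start, end) of the read after removing terminal adapter matches.

    A prefix match compares the adapter's 3' end against the read start (the
    adapter may run off the read's 5' end); a suffix match compares the
    adapter's 5' end against the read end.  Matches shorter than
    ``min_match`` or with more than ``max_mismatch_frac`` mismatching bases
    are ignored; interior occurrences are not searched.
    """
    best_pre = 0
    best_suf = 0
    for ad in adapters:
        for L in range(min(len(ad), len(seq)), min_match - 1, -1):
            if L <= best_pre:
                break
            if _mismatches(ad[-L:], seq[:L]) <= int(max_mismatch_frac * L):
                best_pre = L
                break
        for L in range(min(len(ad), len(seq)), min_match - 1, -1):
            if L <= best_suf:
                break
            if _mismatches(ad[:L], seq[-L:]) <= int(max_mismatch_frac * L):
                best_suf = L
                break
    if best_pre + best_suf >= len(seq):
        return 0, 0
    return best_pre, len(seq) - best_suf


def _tail_run(seq: str, base: str, from_end: bool, min_tail: int) -> int:
    """Longest terminal stretch >= min_tail that is >=90% ``base``.

    Implements "allowing <=1 interruption per 10 bases": a candidate
    terminal window of length L qualifies if it has at most L // 10
    non-``base`` characters and its innermost character is ``base``.
    """
    s = seq[::-1] if from_end else seq
    best = 0
    non = 0
    for L in range(1, len(s) + 1):
        if s[L - 1] != base:
            non += 1
        if L >= min_tail and non <= L // 10 and s[L - 1] == base:
            best = L
    return best


def _polyat_bounds(seq: str, min_tail: int) -> tuple:
    head = _tail_run(seq, "T", from_end=False, min_tail=min_tail)
    tail = _tail_run(seq, "A", from_end=True, min_tail=min_tail)
    if head + tail >= len(seq):
        return 0, 0
    return head, len(seq) - tail


def _resized(read: Read, start: int, end: int) -> Read:
    qual = read.qual[start:end] if read.qual is not None else None
    return replace(read, seq=read.seq[start:end], qual=qual)


def trim_adapters(read: Read, adapters: Iterable[str],
                  max_mismatch_frac: float = 0.1, min_match: int = 8) -> Read:
    """Remove the longest adapter match at either read end (unchanged if none)."""
    adapters = [a.upper() for a in adapters if a]
    if not adapters:
        return read
    start, end = _adapter_bounds(read.seq, adapters, max_mismatch_frac, min_match)
    if start == 0 and end == len(read.seq):
        return read
    if end <= start:
        raise ValueError(f"read {read.id!r}: nothing left after adapter trimming")
    return _resized(read, start, end)


def trim_polyAT(read: Read, min_tail: int = 8) -> Read:
    """Trim a 3' poly-A and/or 5' poly-T tract of length >= ``min_tail``."""
    start, end = _polyat_bounds(read.seq, min_tail)
    if start == 0 and end == len(read.seq):
        return read
    if end <= start:
        raise ValueError(f"read {read.id!r}: nothing left after poly-A/T trimming")
    return _resized(read, start, end)


def screen_contaminants(read: Read, contaminant_index: Optional[align.KmerIndex],
                        min_identity: float = 0.9, min_cov: float = 0.8,
                        params: Optional[align.AlignParams] = None) -> bool:
    """True iff some contaminant alignment covers >= min_cov of the read at >= min_identity."""
    if contaminant_index is None or not contaminant_index.targets:
        return False
    params = params or align.AlignParams(k=contaminant_index.k, min_score=20,
                                         max_evalue=1e3)
    hits = align.search(read.seq, contaminant_index, params, query_id=read.id)
    for h in hits:
        if (h.qend - h.qstart) >= min_cov * len(read.seq) and h.identity >= min_identity:
            return True
    return False


def clean_read(read: Read, config: CleanConfig,
               contaminant_index: Optional[align.KmerIndex] = None) -> tuple:
    """Clean one read; returns ``(read_or_None, category)``.

    Category is one of ``kept``, ``removed_short``, ``removed_contaminant``,
    ``removed_empty``.  The decision depends only on the read itself, so
    collection order never matters.
    """
    adapters = [a.upper() for a in config.adapters if a]
    start, end = 0, len(read.seq)
    if adapters:
        start, end = _adapter_bounds(read.seq, adapters, config.max_mismatch_frac,
                                     config.min_adapter_match)
        if end <= start:
            return None, "removed_empty"
    inner = read.seq[start:end]
    s2, e2 = _polyat_bounds(inner, config.min_tail)
    if e2 <= s2:
        return None, "removed_empty"
    r = _resized(read, start + s2, start + e2)
    if screen_contaminants(r, contaminant_index, config.contaminant_min_identity,
                           config.contaminant_min_cov):
        return None, "removed_contaminant"
    if len(r.seq) < config.min_len:
        return None, "removed_short"
    return r, "kept"


def clean_library(reads: Iterable[Read], config: CleanConfig,
                  contaminants: Optional[dict] = None) -> tuple:
    """Clean a read collection; returns ``(kept_reads, CleanReport)``."""
    index = None
    if contaminants:
        index = align.build_index(contaminants, k=config.contaminant_index_k)
    kept = []
    removed = {"removed_short": 0, "removed_contaminant": 0, "removed_empty": 0}
    raw = 0
    for read in reads:
        raw += 1
        r, category = clean_read(read, config, index)
        if r is not None:
            kept.append(r)
        else:
            removed[category] += 1
    report = CleanReport.tally(raw, **removed)
    assert report.kept == len(kept)
    return kept, report


def pooled_input_total(*counts: int) -> int:
    """Total sequence count entering pre-clustering when datasets are pooled."""
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return sum(counts)
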