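"""Homology screens: retroelement abundance, conserved-ortholog presence, coverage.

Three presence-style analyses share the alignment engine:

* retroelement abundance — nucleotide search of contigs/singletons against a
  retroelement family database at E <= 1e-06; a sequence counts once however
  many elements it hits; the fraction is reported as a percentage with two
  decimals;
* ultraconserved-ortholog (UCO) detection — translated search; a protein is
  detected when some contig hit passes both E <= 1e-10 and an alignment
  length of at least 30 residues; single-copy-tribe detection is the same
  screen at E <= 1e-06 without the residue-length rule;
* comparative transcript coverage — a reference transcript is "represented"
  when at least one contig's best hit lands on it above threshold; the
  percentage is reported to one decimal.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

from . import align


def percent(part: int, whole: int, decimals: int = 1) -> float:
    """100*part/whole truncated at the reporting precision.

    Truncation (not rounding) matches the "represents up to X%" convention
    of coverage reporting: the printed figure never overstates the fraction.
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    scale = 10 ** decimals
    return math.floor(100.0 * part / whole * scale + 1e-9) / scale


def retro_abundance(seqs: Mapping[str, str], retro_db: Mapping[str, str],
                    max_evalue: float = 1e-6,
                    params: Optional[align.AlignParams] = None) -> tuple:
    """Sequences with significant retroelement homology; returns (hit_ids, pct)."""
    if not seqs:
        raise ValueError("empty sequence set")
    if not retro_db:
        return [], 0.0
    params = params or align.AlignParams(k=12, min_score=30)
    params.max_evalue = max_evalue
    index = align.build_index(retro_db, k=params.k)
    hit_ids = []
    for sid, seq in seqs.items():
        hits = align.search(seq, index, params, query_id=sid)
        if any(h.evalue <= max_evalue for h in hits):
            hit_ids.append(sid)
    return hit_ids, percent(len(hit_ids), len(seqs), decimals=2)


def uco_presence(contigs: Mapping[str, str], proteins: Mapping[str, str],
                 max_evalue: float = 1e-10, min_aa_len: int = 30,
                 params: Optional[align.AlignParams] = None) -> tuple:
    """Detected conserved-ortholog proteins: (detected_ids, count, pct).

    A protein is detected if any translated contig hit passes both the
    e-value threshold and the minimum residue alignment length.
    """
    params = params or align.AlignParams()
    params.max_evalue = max_evalue
    index = align.build_protein_index(proteins, k=params.protein_k)
    detected: set = set()
    for cid, seq in contigs.items():
        if len(detected) == len(proteins):
            break
        for h in align.search_translated(seq, index, params, query_id=cid):
            if h.evalue <= max_evalue and h.aln_len >= min_aa_len:
                detected.add(h.target_id)
    frac = percent(len(detected), len(proteins), decimals=1) if proteins else 0.0
    return sorted(detected), len(detected), frac


def tribe_presence(contigs: Mapping[str, str], tribe_representatives: Mapping[str, str],
                   max_evalue: float = 1e-6,
                   params: Optional[align.AlignParams] = None) -> tuple:
    """Single-copy-tribe detection: the UCO screen without the residue-length rule."""
    detected, count, frac = uco_presence(contigs, tribe_representatives,
                                         max_evalue=max_evalue, min_aa_len=0,
                                         params=params)
    return count, frac, detected


def comparative_coverage(contigs: Mapping[str, str], ref_transcripts: Mapping[str, str],
                         max_evalue: float = 1e-6,
                         params: Optional[align.AlignParams] = None) -> tuple:
    """Reference transcripts represented by at least one contig best hit.

    Returns ``(represented_count, pct)`` with the percentage to one decimal.
    """
    if not ref_transcripts:
        raise ValueError("empty reference transcript set")
    params = params or align.AlignParams(k=12, min_score=30)
    params.max_evalue = max_evalue
    index = align.build_index(ref_transcripts, k=params.k)
    represented: set = set()
    for cid, seq in contigs.items():
        best = align.best_hit(align.search(seq, index, params, query_id=cid))
        if best is not None and best.evalue <= max_evalue:
            represented.add(best.target_id)
    return len(represented), percent(len(represented), len(ref_transcripts), decimals=1)


def coverage_fraction_label(represented: int, total: int) -> str:
    """The conventional '79.5%'-style rendering of a coverage fraction."""
    return f"{percent(represented, total, decimals=1):.1f}%"
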