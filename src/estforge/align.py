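"""Seeded local-alignment engine shared by clustering, mapping and screens.

The engine finds exact k-mer seeds against an index, groups seeds into
diagonal bands per target, and resolves each band with an exact local
dynamic-programming alignment (Smith-Waterman with affine gaps, via
Biopython's C aligner) restricted to the seeded target window.  E-values use
the standard Karlin-Altschul form E = K*m*n*exp(-lambda*S) with fixed
constants per score system; they are relative gates within this toolkit, not
NCBI-calibrated statistics.

A translated mode compares all six reading frames of a nucleotide query
(frames truncated at stop codons) against a protein database, scoring with
BLOSUM62; it stands in for a tblastx/blastx-style screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import AlignmentHit

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignParams:
    """Scoring and gating parameters for the engine.

    Nucleotide defaults approximate BLASTN (+1/-2, gaps -5/-2, word 11);
    ``kaltschul_k``/``kaltschul_lambda`` are the fixed E-value constants for
    that score system.  ``max_evalue`` carries the screen thresholds
    (1e-06 for retroelement/tribe screens, 1e-10 for the conserved-ortholog
    screen).
    """

    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: float = 25.0
    max_evalue: float = 10.0
    kaltschul_k: float = 0.13
    kaltschul_lambda: float = 0.55
    # protein (translated) mode
    protein_k: int = 4
    protein_gap_open: int = -11
    protein_gap_extend: int = -1
    protein_kaltschul_k: float = 0.041
    protein_kaltschul_lambda: float = 0.267
    protein_min_score: float = 40.0
    seed_step: int = 1
    band_pad: int = 24

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("seed length k must be >= 4")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass
class KmerIndex:
    """Exact k-mer index over a set of target sequences (forward strand)."""

    k: int
    targets: dict
    index: dict = field(default_factory=dict)
    total_len: int = 0

    def target_len(self, tid: str) -> int:
        return len(self.targets[tid])


def build_index(targets: Mapping[str, str], k: int = 11) -> KmerIndex:
    """Index every exact k-mer position of every target.

    Targets shorter than ``k`` contribute no seeds (they can still be hit
    through other targets' windows only if identical, so callers screening
    tiny targets should lower ``k``).
    """
    idx = KmerIndex(k=k, targets=dict(targets))
    for tid, seq in idx.targets.items():
        idx.total_len += len(seq)
        for pos in range(0, len(seq) - k + 1):
            word = seq[pos:pos + k]
            if "N" in word:
                continue
            idx.index.setdefault(word, []).append((tid, pos))
    return idx


def evalue(score: float, query_len: int, db_len: int, params: AlignParams,
           protein: bool = False) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if protein:
        K, lam = params.protein_kaltschul_k, params.protein_kaltschul_lambda
    else:
        K, lam = params.kaltschul_k, params.kaltschul_lambda
    return K * query_len * db_len * math.exp(-lam * score)


def _nucl_aligner(params: AlignParams) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def _protein_aligner(params: AlignParams) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = params.protein_gap_open
    a.extend_gap_score = params.protein_gap_extend
    return a


def _alignment_to_hit(aln, qid, tid, strand, qlen, win_off, db_len, params) -> Optional[AlignmentHit]:
    segs_q, segs_t = aln.aligned
    if len(segs_q) == 0:
        return None
    qs, qe = int(segs_q[0][0]), int(segs_q[-1][1])
    ts, te = int(segs_t[0][0]) + win_off, int(segs_t[-1][1]) + win_off
    counts = aln.counts()
    matches = int(counts.identities)
    aln_len = int(counts.identities + counts.mismatches + counts.gaps)
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    ev = evalue(aln.score, qlen, db_len, params)
    return AlignmentHit(query_id=qid, target_id=tid, qstart=qs, qend=qe,
                        tstart=ts, tend=te, strand=strand, matches=matches,
                        aln_len=aln_len, score=float(aln.score), evalue=ev)


def _seed_bands(q: str, index: KmerIndex, step: int):
    """Group seed hits into per-target diagonal bands: {tid: [(tlo, thi)]}."""
    k = index.k
    diags: dict = {}
    for qpos in range(0, len(q) - k + 1, step):
        word = q[qpos:qpos + k]
        for tid, tpos in index.index.get(word, ()):
            diags.setdefault(tid, []).append((tpos - qpos, tpos))
    bands = {}
    for tid, hits in diags.items():
        hits.sort()
        groups = []
        cur = [hits[0]]
        for d, tpos in hits[1:]:
            if d - cur[-1][0] <= 2 * k:
                cur.append((d, tpos))
            else:
                groups.append(cur)
                cur = [(d, tpos)]
        groups.append(cur)
        bands[tid] = [(min(t for _, t in g), max(t for _, t in g) + k) for g in groups]
    return bands


def _dedupe(hits: list) -> list:
    """Drop hits mostly contained in a better hit on the same target/strand."""
    hits.sort(key=lambda h: (-h.score, h.target_id, h.tstart))
    kept: list = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.target_id != h.target_id or g.strand != h.strand:
                continue
            ov = min(g.tend, h.tend) - max(g.tstart, h.tstart)
            if ov > 0 and ov >= 0.5 * (h.tend - h.tstart):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search(query: str, index: KmerIndex, params: AlignParams = AlignParams(),
           query_id: str = "query", mode: str = "nucl") -> list:
    """Local-align ``query`` against every indexed target, both strands.

    Returns qualifying hits (score >= min_score, evalue <= max_evalue)
    sorted by descending score then target id.  ``mode='translated'`` is
    served by :func:`search_translated` and expects a protein index built
    with :func:`build_protein_index`.
    """
    if mode == "translated":
        return search_translated(query, index, params, query_id=query_id)
    aligner = _nucl_aligner(params)
    qlen = len(query)
    out = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        for tid, band_list in _seed_bands(q, index, params.seed_step).items():
            tseq = index.targets[tid]
            windows = []
            for tlo, thi in band_list:
                lo = max(0, tlo - qlen - params.band_pad)
                hi = min(len(tseq), thi + qlen + params.band_pad)
                if windows and lo <= windows[-1][1]:
                    windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
                else:
                    windows.append((lo, hi))
            for lo, hi in windows:
                alns = aligner.align(q, tseq[lo:hi])
                if len(alns) == 0:
                    continue
                hit = _alignment_to_hit(alns[0], query_id, tid, strand, qlen,
                                        lo, index.total_len, params)
                if hit is None:
                    continue
                if hit.score >= params.min_score and hit.evalue <= params.max_evalue:
                    out.append(hit)
    out = _dedupe(out)
    out.sort(key=lambda h: (-h.score, h.target_id, h.tstart))
    return out


def best_hit(hits: Iterable[AlignmentHit]) -> Optional[AlignmentHit]:
    """The single best hit by score; ties by higher identity, then smallest target id."""
    best = None
    for h in hits:
        if best is None:
            best = h
            continue
        key_h = (-h.score, -h.identity, h.target_id)
        key_b = (-best.score, -best.identity, best.target_id)
        if key_h < key_b:
            best = h
    return best


# ---------------------------------------------------------------------------
# Translated mode
# ---------------------------------------------------------------------------

def six_frame_peptides(seq: str, min_len: int = 8) -> list:
    """Peptides from all 6 frames, split at stop codons.

    Returns ``(frame, aa_offset, peptide)`` where ``frame`` is 1..3 forward,
    -1..-3 reverse, and ``aa_offset`` is the peptide's offset (in residues)
    within the frame translation.
    """
    peptides = []
    for sign, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            start = 0
            for part in aa.split("*"):
                if len(part) >= min_len:
                    peptides.append((sign * (off + 1), start, part))
                start += len(part) + 1
    return peptides


@dataclass
class ProteinIndex:
    """4-mer presence index over a protein database (prefilter for DP)."""

    k: int
    targets: dict
    words: dict = field(default_factory=dict)  # word -> set of target ids
    total_len: int = 0


def build_protein_index(proteins: Mapping[str, str], k: int = 4) -> ProteinIndex:
    idx = ProteinIndex(k=k, targets=dict(proteins))
    for tid, seq in idx.targets.items():
        idx.total_len += len(seq)
        for pos in range(0, len(seq) - k + 1):
            idx.words.setdefault(seq[pos:pos + k], set()).add(tid)
    return idx


def search_translated(query_nt: str, index: ProteinIndex,
                      params: AlignParams = AlignParams(),
                      query_id: str = "query") -> list:
    """Six-frame translated search of a nucleotide query vs a protein index.

    Hit coordinates: query interval in nucleotides on the forward query
    strand; target interval in residues.  ``aln_len``/``matches`` count
    amino-acid columns (used by the >=30-residue alignment-length rule).
    """
    aligner = _protein_aligner(params)
    k = index.k
    qlen = len(query_nt)
    out = []
    for frame, aa_off, pep in six_frame_peptides(query_nt):
        cand: set = set()
        for pos in range(0, len(pep) - k + 1):
            cand |= index.words.get(pep[pos:pos + k], set())
        for tid in sorted(cand):
            alns = aligner.align(pep, index.targets[tid])
            if len(alns) == 0:
                continue
            aln = alns[0]
            segs_q, segs_t = aln.aligned
            if len(segs_q) == 0:
                continue
            counts = aln.counts()
            matches = int(counts.identities)
            aln_len = int(counts.identities + counts.mismatches + counts.gaps)
            ev = evalue(aln.score, max(1, qlen // 3), index.total_len, params, protein=True)
            if aln.score < params.protein_min_score or ev > params.max_evalue:
                continue
            ps, pe = int(segs_q[0][0]), int(segs_q[-1][1])
            # residue coords within the frame translation -> nt coords on query
            aa_s, aa_e = aa_off + ps, aa_off + pe
            off = abs(frame) - 1
            if frame > 0:
                qs, qe = off + 3 * aa_s, off + 3 * aa_e
            else:
                qs, qe = qlen - (off + 3 * aa_e), qlen - (off + 3 * aa_s)
            qs, qe = max(0, qs), min(qlen, qe)
            out.append(AlignmentHit(
                query_id=query_id, target_id=tid, qstart=qs, qend=qe,
                tstart=int(segs_t[0][0]), tend=int(segs_t[-1][1]),
                strand="+" if frame > 0 else "-", matches=matches,
                aln_len=aln_len, score=float(aln.score), evalue=ev))
    out.sort(key=lambda h: (-h.score, h.target_id, h.tstart))
    return out


def hits_to_table(hits: Iterable[AlignmentHit]):
    """The 12 canonical tabular columns for a hit list."""
    import pandas as pd

    rows = [{
        "query_id": h.query_id, "target_id": h.target_id,
        "identity": round(100.0 * h.identity, 2), "aln_len": h.aln_len,
        "mismatches": h.aln_len - h.matches,
        "qstart": h.qstart, "qend": h.qend,
        "tstart": h.tstart, "tend": h.tend,
        "strand": h.strand, "evalue": h.evalue, "score": h.score,
    } for h in hits]
    return pd.DataFrame(rows, columns=[
        "query_id", "target_id", "identity", "aln_len", "mismatches",
        "qstart", "qend", "tstart", "tend", "strand", "evalue", "score"])
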