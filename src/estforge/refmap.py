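"""Reference-guided path: locus assignment, re-assembly by locus, binned coverage.

Queries (contigs or singleton reads) are assigned to the reference by their
single best alignment (highest score; ties by identity, then target id),
clustered by single-linkage interval overlap on the same chromosome and
strand, and each locus group is re-assembled.  Coverage is summarized in
fixed-width bins (default 0.5 Mb): assignment *counts* go to the bin holding
the interval midpoint, while aligned bases are split exactly across bins so
that sum(mean depth x bin span) equals the total aligned bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from . import align
from .cluster_assemble import AssemblyResult, _build_backbone, _vote
from .seqio import BinnedCoverage, Contig


@dataclass
class LocusAssignment:
    """Best-hit placement of one query on the reference."""

    query_id: str
    chrom: str
    tstart: int
    tend: int
    strand: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.tstart >= self.tend:
            raise ValueError(f"{self.query_id}: empty reference interval")


def assign_to_reference(queries: Mapping[str, str], genome_index: align.KmerIndex,
                        params: Optional[align.AlignParams] = None) -> tuple:
    """Best-hit locus per query; returns ``(assignments, unassigned_ids)``."""
    params = params or align.AlignParams(k=genome_index.k, min_score=30,
                                         max_evalue=1e-6)
    assignments = []
    unassigned = []
    for qid, seq in queries.items():
        hits = align.search(seq, genome_index, params, query_id=qid)
        best = align.best_hit(hits)
        if best is None:
            unassigned.append(qid)
            continue
        if best.tend > genome_index.target_len(best.target_id):
            raise ValueError(f"{qid}: hit beyond end of {best.target_id}")
        assignments.append(LocusAssignment(
            query_id=qid, chrom=best.target_id, tstart=best.tstart,
            tend=best.tend, strand=best.strand, score=best.score,
            identity=best.identity))
    return assignments, unassigned


def _locus_groups(assignments: Iterable[LocusAssignment]) -> list:
    """Single-linkage interval-overlap clusters per (chrom, strand)."""
    by_key: dict = {}
    for a in assignments:
        by_key.setdefault((a.chrom, a.strand), []).append(a)
    groups = []
    for key in sorted(by_key):
        items = sorted(by_key[key], key=lambda a: (a.tstart, a.query_id))
        cur = [items[0]]
        cur_end = items[0].tend
        for a in items[1:]:
            if a.tstart < cur_end:          # >= 1 bp overlap
                cur.append(a)
                cur_end = max(cur_end, a.tend)
            else:
                groups.append(cur)
                cur = [a]
                cur_end = a.tend
        groups.append(cur)
    return groups


def reference_guided_assemble(queries: Mapping[str, str], genome: Mapping[str, str],
                              align_params: Optional[align.AlignParams] = None,
                              genome_index: Optional[align.KmerIndex] = None,
                              members_map: Optional[Mapping[str, list]] = None,
                              weights: Optional[Mapping[str, np.ndarray]] = None,
                              ) -> tuple:
    """Cluster queries by overlapping reference loci and assemble each group.

    The reference supplies layout (orientation from the assigned strand,
    offsets from the assigned interval); the consensus is voted from the
    queries themselves, so reference bases never leak into contigs.
    Unassigned queries become singletons.  Returns
    ``(AssemblyResult, assignments)``.
    """
    genome_index = genome_index or align.build_index(genome, k=13)
    assignments, unassigned = assign_to_reference(queries, genome_index, align_params)
    members_map = members_map or {}
    weights = weights or {}

    def mm_of(sid):
        return members_map.get(sid, [(sid, 0, "+")])

    def w_of(sid):
        w = weights.get(sid)
        return w if w is not None else np.ones(len(queries[sid]), dtype=np.int64)

    contigs = []
    n = 0
    for group in _locus_groups(assignments):
        if len(group) == 1:
            sid = group[0].query_id
            contigs.append(Contig(id=f"ref_{n}", consensus=queries[sid],
                                  members=list(mm_of(sid)), depth=w_of(sid)))
            n += 1
            continue
        base = min(a.tstart for a in group)
        oriented = []
        for a in sorted(group, key=lambda a: (a.tstart, a.query_id)):
            flip = 0 if a.strand == "+" else 1
            seq = queries[a.query_id]
            oseq = seq if flip == 0 else align.revcomp(seq)
            w_or = w_of(a.query_id) if flip == 0 else w_of(a.query_id)[::-1]
            oriented.append((a.query_id, oseq, a.tstart - base, w_or, flip))
        backbone = _build_backbone([(sid, oseq, pos) for sid, oseq, pos, _, _ in oriented])
        consensus, depth, locs = _vote(backbone,
                                       [(sid, oseq, w_or) for sid, oseq, _, w_or, _ in oriented])
        mem = []
        seen = set()
        for sid, oseq, pos, w_or, flip in oriented:
            start = locs.get(sid, pos)
            for rid, off, st in mm_of(sid):
                if rid in seen:
                    continue
                seen.add(rid)
                if flip == 0:
                    new_off, new_st = start + off, st
                else:
                    new_off = start + max(0, len(oseq) - off - 1)
                    new_st = "-" if st == "+" else "+"
                new_off = min(max(new_off, 0), max(0, len(consensus) - 1))
                mem.append((rid, new_off, new_st))
        contigs.append(Contig(id=f"ref_{n}", consensus=consensus, members=mem, depth=depth))
        n += 1
    final_contigs = []
    singletons = []
    for c in contigs:
        if len({rid for rid, _, _ in c.members}) >= 2:
            final_contigs.append(c)
        else:
            singletons.append(c.members[0][0])
    for qid in unassigned:
        singletons.extend(rid for rid, _, _ in mm_of(qid))
    result = AssemblyResult(contigs=final_contigs, singletons=sorted(set(singletons)))
    return result, assignments


def binned_coverage(assignments: Iterable[LocusAssignment], genome: Mapping[str, str],
                    bin_width: int = 500_000,
                    tracks: Optional[Mapping[str, str]] = None) -> list:
    """Strand- and track-separated binned counts and exact per-bin aligned bases.

    ``tracks`` maps query id to a track label (e.g. ``contig`` vs
    ``singleton``); unknown queries default to ``contig``.  Counts use the
    interval midpoint's bin; aligned bases are split exactly where an
    alignment spans a bin boundary.
    """
    tracks = tracks or {}
    covs = {chrom: BinnedCoverage(chrom=chrom, chrom_len=len(seq), bin_width=bin_width)
            for chrom, seq in genome.items()}
    for a in assignments:
        if a.chrom not in covs:
            raise ValueError(f"assignment {a.query_id}: unknown chromosome {a.chrom}")
        cov = covs[a.chrom]
        if a.tend > cov.chrom_len:
            raise ValueError(f"assignment {a.query_id}: interval beyond end of {a.chrom}")
        track = tracks.get(a.query_id, "contig")
        key = (a.strand, track)
        if key not in cov.counts:
            cov.counts[key] = np.zeros(cov.n_bins, dtype=np.int64)
            cov.aligned_bases[key] = np.zeros(cov.n_bins, dtype=np.int64)
        mid = (a.tstart + a.tend) // 2
        cov.counts[key][mid // bin_width] += 1
        b = a.tstart // bin_width
        pos = a.tstart
        while pos < a.tend:
            bin_end = (b + 1) * bin_width
            chunk = min(a.tend, bin_end) - pos
            cov.aligned_bases[key][b] += chunk
            pos += chunk
            b += 1
    return [covs[chrom] for chrom in sorted(covs)]


def coverage_table(covs: Iterable[BinnedCoverage]):
    """Circos-style long table: chrom, bin_start, bin_end, strand, track, count, mean_depth."""
    import pandas as pd

    rows = []
    for cov in covs:
        for (strand, track) in sorted(cov.counts):
            counts = cov.counts[(strand, track)]
            depth = cov.mean_depth(strand, track)
            for b in range(cov.n_bins):
                rows.append({
                    "chrom": cov.chrom,
                    "bin_start": b * cov.bin_width,
                    "bin_end": b * cov.bin_width + cov.bin_span(b),
                    "strand": strand,
                    "track": track,
                    "count": int(counts[b]),
                    "mean_depth": float(depth[b]),
                })
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "strand",
                                       "track", "count", "mean_depth"])
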