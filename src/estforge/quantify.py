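"""Expression profiling: shred reads to 40-mers, map to contigs, RPKM, clustering.

Long reads are shredded into non-overlapping 40-bp fragments (the terminal
remainder is discarded), each fragment is assigned to the contig position
(either strand) with the fewest mismatches up to a cap, and per-library
counts are converted to RPKM = count x 1e9 / (length_bp x total_mapped).
Detection and clustering subsets follow the standard filters: contigs below
1 RPKM in every library are dropped from the detected set, and the
clustering subset keeps contigs above 10 RPKM in at least one library.
Profiles are log2(RPKM + 1) transformed and clustered by average-linkage
(UPGMA) hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .align import revcomp
from .seqio import ExpressionRecord, Read


@dataclass
class QuantParams:
    fragment_len: int = 40
    max_mismatches: int = 2
    rpkm_detect_min: float = 1.0
    rpkm_cluster_min: float = 10.0
    log_offset: float = 1.0
    seed_k: int = 13

    def __post_init__(self) -> None:
        if self.fragment_len < 20:
            raise ValueError("fragment_len must be >= 20")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class Fragment:
    read_id: str
    ordinal: int
    seq: str
    library: str

    @property
    def id(self) -> str:
        return f"{self.read_id}/{self.ordinal}"


def shred(read: Read, fragment_len: int = 40) -> list:
    """Non-overlapping tiling from position 0; remainder < fragment_len dropped."""
    frags = []
    for ordinal, start in enumerate(range(0, len(read.seq) - fragment_len + 1,
                                          fragment_len)):
        frags.append(Fragment(read_id=read.id, ordinal=ordinal,
                              seq=read.seq[start:start + fragment_len],
                              library=read.library))
    return frags


def shred_collection(reads: Iterable[Read], fragment_len: int = 40) -> list:
    out = []
    for r in reads:
        out.extend(shred(r, fragment_len))
    return out


@dataclass
class MappingResult:
    counts: pd.DataFrame          # contigs x libraries, int
    total_mapped: dict            # library -> int
    total_fragments: dict         # library -> int (mapped + unmapped)
    unmapped: dict                # library -> int


def _hamming(a: str, b: str, cap: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > cap:
                return m
    return m


def map_fragments(fragments: Iterable[Fragment], contigs: Mapping[str, str],
                  params: QuantParams = QuantParams(),
                  libraries: Optional[Sequence[str]] = None) -> MappingResult:
    """Assign each fragment to its fewest-mismatch contig position (either strand).

    Candidate positions come from exact k-mer anchors at fragment offsets
    0, k, 2k (pigeonhole: with <= 2 mismatches in 40 bp at k=13 one piece is
    exact). Ties across contigs go to the lexicographically smallest contig
    id; fragments worse than ``max_mismatches`` everywhere count as unmapped.
    """
    k = params.seed_k
    index: dict = {}
    for cid, seq in contigs.items():
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((cid, pos))
    cids = sorted(contigs)
    fragments = list(fragments)
    if libraries is None:
        libraries = sorted({f.library for f in fragments}) or ["other"]
    counts = {cid: {lib: 0 for lib in libraries} for cid in cids}
    total_fragments = {lib: 0 for lib in libraries}
    unmapped = {lib: 0 for lib in libraries}
    fl = params.fragment_len
    anchor_offsets = [o for o in range(0, fl - k + 1, k)]
    for frag in fragments:
        total_fragments[frag.library] += 1
        best: Optional[tuple] = None            # (mismatches, cid)
        for fseq in (frag.seq, revcomp(frag.seq)):
            seen = set()
            for off in anchor_offsets:
                word = fseq[off:off + k]
                for cid, pos in index.get(word, ()):
                    start = pos - off
                    if start < 0 or start + fl > len(contigs[cid]):
                        continue
                    if (cid, start) in seen:
                        continue
                    seen.add((cid, start))
                    mm = _hamming(fseq, contigs[cid][start:start + fl],
                                  params.max_mismatches)
                    if mm > params.max_mismatches:
                        continue
                    cand = (mm, cid)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            unmapped[frag.library] += 1
        else:
            counts[best[1]][frag.library] += 1
    df = pd.DataFrame(counts).T.reindex(cids)
    df = df[list(libraries)].astype(int) if len(df) else df
    total_mapped = {lib: int(df[lib].sum()) if len(df) else 0 for lib in libraries}
    return MappingResult(counts=df, total_mapped=total_mapped,
                         total_fragments=total_fragments, unmapped=unmapped)


def rpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (length_bp * total_mapped)


@dataclass
class ExpressionMatrix:
    """Contigs x libraries RPKM with detection/clustering subsets."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    lengths: dict
    total_mapped: dict
    detect_min: float
    cluster_min: float

    @property
    def detected(self) -> pd.DataFrame:
        keep = (self.rpkm >= self.detect_min).any(axis=1)
        return self.rpkm[keep]

    @property
    def clustering_subset(self) -> pd.DataFrame:
        keep = (self.rpkm > self.cluster_min).any(axis=1)
        return self.rpkm[keep]

    @property
    def expressed_per_library(self) -> pd.Series:
        return (self.detected >= self.detect_min).sum(axis=0)

    def records(self) -> list:
        out = []
        for cid in self.rpkm.index:
            out.append(ExpressionRecord(
                contig_id=cid, length_bp=self.lengths[cid],
                counts=self.counts.loc[cid].to_dict(),
                rpkm=self.rpkm.loc[cid].to_dict()))
        return out


def build_matrix(mapping: MappingResult, lengths: Mapping[str, int],
                 params: QuantParams = QuantParams()) -> ExpressionMatrix:
    """RPKM per contig x library from mapped-fragment counts."""
    counts = mapping.counts
    data = {}
    for lib in counts.columns:
        total = mapping.total_mapped[lib]
        if total > 0:
            data[lib] = [rpkm(int(counts.at[cid, lib]), lengths[cid], total)
                         for cid in counts.index]
        else:
            data[lib] = [0.0] * len(counts.index)
    df = pd.DataFrame(data, index=counts.index)
    return ExpressionMatrix(rpkm=df, counts=counts, lengths=dict(lengths),
                            total_mapped=dict(mapping.total_mapped),
                            detect_min=params.rpkm_detect_min,
                            cluster_min=params.rpkm_cluster_min)


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Entrywise log2(x + offset); rejects negative entries."""
    if (matrix.values < 0).any():
        raise ValueError("expression matrix contains negative entries")
    return np.log2(matrix + offset)


def average_linkage_cluster(matrix: pd.DataFrame, axis: str = "rows") -> tuple:
    """UPGMA (average-linkage) clustering on Euclidean distances.

    Returns ``(linkage_matrix, labels)`` in scipy's merge-tree encoding.
    """
    data = matrix if axis == "rows" else matrix.T
    if len(data) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(data.values, method="average", metric="euclidean")
    return Z, list(data.index)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"
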