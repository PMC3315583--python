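"""De novo path: overlap detection, multi-membership pre-clustering, iterative assembly.

The pipeline mirrors classic EST practice for a polyploid transcriptome:

1. all-versus-all overlap detection (k-mer seeded, banded edit-distance
   verification) keeping dovetail/containment overlaps above a length and
   identity floor;
2. *multi-membership* pre-clustering: reads are sorted by descending length,
   each not-yet-clustered read seeds a cluster, and every read overlapping
   the seed joins that cluster regardless of prior membership — so a read
   bridging two diverged paralog families legitimately lands in both
   clusters instead of forcing the families into one consensus;
3. per-cluster greedy overlap layout and per-column weighted majority-vote
   consensus (ties become IUPAC codes, a gap majority deletes the column);
4. iteration: several refinement cycles re-overlap and re-assemble the
   previous cycle's contigs plus leftover singletons, followed by one final
   stricter merge cycle.  Contig membership is traced through every cycle,
   so contigs always list original read ids.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import edlib
import numpy as np
import pandas as pd

from .align import revcomp
from .seqio import Cluster, Contig

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class OverlapParams:
    """Overlap/assembly thresholds.

    Defaults (40 bp at 94% identity; merge cycle 40 bp at 97%) approximate
    common MIRA/CAP3 practice; ``cycles`` refinement passes are followed by
    one stricter merge pass when ``merge`` is true.
    """

    min_overlap_len: int = 40
    min_overlap_identity: float = 0.94
    merge_overlap_len: int = 40
    merge_identity: float = 0.97
    cycles: int = 4
    merge: bool = True
    index_k: int = 16
    seed_step: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap_identity <= 1.0:
            raise ValueError("identity must be in (0,1]")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


@dataclass
class Overlap:
    """A dovetail/containment overlap between sequences ``a`` and ``b``.

    ``strand`` says whether ``b`` is reverse-complemented relative to ``a``;
    with ``b_or`` the oriented b, the relation is ``a[i] ~ b_or[i + d]``
    (so oriented b starts at a-coordinate ``-d``).
    """

    a: str
    b: str
    strand: str
    d: int
    length: int
    identity: float

    @property
    def score(self) -> float:
        return self.length * self.identity

    def edge_from(self, node: str, len_a: int, len_b: int) -> tuple:
        """``(other, strand_rel, start)``: start of oriented-other in node-forward frame."""
        if node == self.a:
            return self.b, self.strand, -self.d
        if self.strand == "+":
            return self.a, "+", self.d
        return self.a, "-", len_b - len_a - self.d


def _cigar_walk(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _verify_overlap(a: str, b_or: str, d: int, min_len: int, min_ident: float):
    """Check the implied overlap with a banded edit-distance alignment."""
    a_s = max(0, -d)
    a_e = min(len(a), len(b_or) - d)
    L = a_e - a_s
    if L < min_len:
        return None
    pad = 10 + L // 20
    sb = b_or[max(0, a_s + d - pad): min(len(b_or), a_e + d + pad)]
    sa = a[a_s:a_e]
    limit = int((1.0 - min_ident) * 2 * L) + 10
    res = edlib.align(sa, sb, mode="HW", task="path", k=limit)
    if res["editDistance"] < 0:
        return None
    cols = sum(n for n, _ in _cigar_walk(res["cigar"]))
    ident = 1.0 - res["editDistance"] / cols
    if ident < min_ident:
        return None
    return L, ident


def find_overlaps(seqs: Mapping[str, str], params: OverlapParams = OverlapParams(),
                  min_len: Optional[int] = None,
                  min_identity: Optional[float] = None) -> list:
    """All-vs-all dovetail/containment overlaps meeting the thresholds.

    Symmetric by construction (each unordered pair examined once); self
    pairs excluded.
    """
    min_len = params.min_overlap_len if min_len is None else min_len
    min_ident = params.min_overlap_identity if min_identity is None else min_identity
    ids = list(seqs)
    k = params.index_k
    index: dict = {}
    for j, sid in enumerate(ids):
        s = seqs[sid]
        for pos in range(0, len(s) - k + 1):
            word = s[pos:pos + k]
            if "N" not in word:
                index.setdefault(word, []).append((j, pos))
    overlaps = []
    for i, aid in enumerate(ids):
        a = seqs[aid]
        cand: dict = {}
        for strand in "+-":
            q = a if strand == "+" else revcomp(a)
            for qpos in range(0, len(q) - k + 1, params.seed_step):
                word = q[qpos:qpos + k]
                if "N" in word:
                    continue
                for j, tpos in index.get(word, ()):
                    if j <= i:
                        continue
                    cand.setdefault((j, strand), []).append(tpos - qpos)
        best: dict = {}
        for (j, strand), diags in cand.items():
            bid = ids[j]
            b = seqs[bid]
            diags.sort()
            groups = [[diags[0]]]
            for dd in diags[1:]:
                if dd - groups[-1][-1] <= 30:
                    groups[-1].append(dd)
                else:
                    groups.append([dd])
            for g in groups:
                d_seed = g[len(g) // 2]
                if strand == "+":
                    d = d_seed
                    b_or = b
                else:
                    d = len(b) - len(a) - d_seed
                    b_or = revcomp(b)
                got = _verify_overlap(a, b_or, d, min_len, min_ident)
                if got is None:
                    continue
                L, ident = got
                ov = Overlap(a=aid, b=bid, strand=strand, d=d, length=L, identity=ident)
                if j not in best or ov.score > best[j].score:
                    best[j] = ov
        overlaps.extend(best.values())
    return overlaps


def precluster(seqs: Mapping[str, str], overlaps: Iterable[Overlap]) -> list:
    """Seed-based greedy multi-membership clustering.

    Reads are visited by descending length (ties by id).  Each read not yet
    a member of any cluster seeds a new cluster; every read directly
    overlapping the seed joins that cluster regardless of prior membership.
    """
    adj: dict = {}
    for ov in overlaps:
        adj.setdefault(ov.a, set()).add(ov.b)
        adj.setdefault(ov.b, set()).add(ov.a)
    clusters = []
    member_anywhere: set = set()
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    for sid in order:
        if sid in member_anywhere:
            continue
        members = {sid} | adj.get(sid, set())
        clusters.append(Cluster(id=f"cl{len(clusters):05d}", seed=sid, members=members))
        member_anywhere |= members
    return clusters


# ---------------------------------------------------------------------------
# Layout and consensus
# ---------------------------------------------------------------------------

def _components(members: set, edges: list) -> list:
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ov in edges:
        ra, rb = find(ov.a), find(ov.b)
        if ra != rb:
            parent[ra] = rb
    comps: dict = {}
    for m in members:
        comps.setdefault(find(m), []).append(m)
    return [sorted(v) for v in comps.values()]


def _orient_and_place(comp: list, edges: list, lengths: dict) -> tuple:
    """BFS orientation/offset assignment; returns (placement, demoted).

    placement: {sid: (flip, pos)}; reads whose orientation conflicts along
    a cycle are demoted (returned separately, each becomes its own contig).
    """
    adj: dict = {m: [] for m in comp}
    for ov in edges:
        adj[ov.a].append(ov)
        adj[ov.b].append(ov)
    placement: dict = {}
    demoted: list = []
    start = comp[0]
    placement[start] = (0, 0)
    queue = deque([start])
    while queue:
        node = queue.popleft()
        flip_n, pos_n = placement[node]
        ln = lengths[node]
        for ov in adj[node]:
            other, strand_rel, s = ov.edge_from(node, lengths[ov.a], lengths[ov.b])
            lo = lengths[other]
            if flip_n == 0:
                flip_o = 0 if strand_rel == "+" else 1
                pos_o = pos_n + s
            else:
                flip_o = 1 if strand_rel == "+" else 0
                pos_o = pos_n + ln - s - lo
            if other in placement:
                if placement[other][0] != flip_o and other not in demoted:
                    demoted.append(other)
                continue
            placement[other] = (flip_o, pos_o)
            queue.append(other)
    for sid in demoted:
        placement.pop(sid, None)
    shift = min(p for _, p in placement.values())
    placement = {sid: (f, p - shift) for sid, (f, p) in placement.items()}
    return placement, demoted


def _build_backbone(placed: list) -> str:
    """Chain oriented sequences left to right, refining junctions with edlib."""
    backbone = ""
    cur_end = 0
    for sid, oseq, pos in placed:
        if not backbone:
            backbone = oseq
            cur_end = pos + len(oseq)
            continue
        if pos >= cur_end:                      # defensive: disconnected layout
            backbone += "N" * (pos - cur_end) + oseq
            cur_end = pos + len(oseq)
            continue
        ov_est = cur_end - pos
        if ov_est >= len(oseq):
            continue                            # contained, nothing to extend
        probe_s = max(0, ov_est - 120)
        probe = oseq[probe_s:ov_est]
        tail_s = max(0, len(backbone) - (ov_est - probe_s) - 60)
        res = edlib.align(probe, backbone[tail_s:], mode="HW", task="locations",
                          k=max(10, len(probe) // 4))
        if res["editDistance"] >= 0 and res["locations"]:
            cut = tail_s + res["locations"][0][1] + 1
            backbone = backbone[:cut] + oseq[ov_est:]
        else:
            backbone += oseq[ov_est:]
        cur_end = len(backbone)
    return backbone


def _vote(backbone: str, placed_full: list) -> tuple:
    """Per-column weighted vote of every member against the backbone.

    Returns (consensus, depth, locations) where locations maps member id to
    its start on the backbone.  Insertions relative to the backbone are
    dropped; a gap-majority column is deleted.
    """
    n = len(backbone)
    votes = np.zeros((5, n), dtype=np.int64)    # A C G T gap
    cov = np.zeros(n, dtype=np.int64)
    locations: dict = {}
    for sid, oseq, w_or in placed_full:
        res = edlib.align(oseq, backbone, mode="HW", task="path",
                          k=max(20, len(oseq) // 3))
        if res["editDistance"] < 0:
            res = edlib.align(oseq, backbone, mode="HW", task="path")
        tpos = res["locations"][0][0]
        locations[sid] = tpos
        qpos = 0
        for num, op in _cigar_walk(res["cigar"]):
            if op in "=XM":
                for t in range(num):
                    base = oseq[qpos + t]
                    wgt = int(w_or[qpos + t])
                    bi = _BASE_IDX.get(base)
                    if bi is not None:
                        votes[bi, tpos + t] += wgt
                    cov[tpos + t] += wgt
                qpos += num
                tpos += num
            elif op == "I":
                qpos += num
            elif op == "D":
                wgt = int(w_or[min(qpos, len(w_or) - 1)])
                votes[4, tpos:tpos + num] += wgt
                cov[tpos:tpos + num] += wgt
                tpos += num
    cons = []
    depth = []
    for col in range(n):
        total = cov[col]
        if total == 0:
            cons.append("N")
            depth.append(0)
            continue
        if votes[4, col] * 2 > total:
            continue                            # gap majority: delete column
        col_votes = votes[:4, col]
        m = col_votes.max()
        if m == 0:
            cons.append("N")
            depth.append(int(total))
            continue
        tied = frozenset("ACGT"[i] for i in range(4) if col_votes[i] == m)
        cons.append(_IUPAC[tied])
        depth.append(int(total))
    return "".join(cons), np.array(depth, dtype=np.int64), locations


def layout_and_consensus(cluster: Cluster, seqs: Mapping[str, str],
                         params: OverlapParams = OverlapParams(),
                         overlaps: Optional[Iterable[Overlap]] = None,
                         weights: Optional[Mapping[str, np.ndarray]] = None,
                         members_map: Optional[Mapping[str, list]] = None,
                         prefix: Optional[str] = None) -> list:
    """Assemble one cluster into contigs.

    ``weights`` carries per-column read depth of each input sequence (ones
    for raw reads); ``members_map`` maps each input sequence to its original
    read membership, so returned contigs always list original read ids.
    The cluster is split wherever no qualifying overlap connects components;
    single-member components come back as single-member contigs.
    """
    prefix = prefix if prefix is not None else f"{cluster.id}_"
    members = set(cluster.members)
    if overlaps is None:
        sub = {sid: seqs[sid] for sid in members}
        overlaps = find_overlaps(sub, params)
    edges = [ov for ov in overlaps if ov.a in members and ov.b in members]
    weights = weights or {}
    members_map = members_map or {}
    lengths = {sid: len(seqs[sid]) for sid in members}

    def w_of(sid):
        w = weights.get(sid)
        return w if w is not None else np.ones(lengths[sid], dtype=np.int64)

    def mm_of(sid):
        return members_map.get(sid, [(sid, 0, "+")])

    contigs = []
    n = 0
    for comp in _components(members, edges):
        singles = []
        if len(comp) == 1:
            singles = comp
            placement = {}
        else:
            comp_edges = [ov for ov in edges if ov.a in comp and ov.b in comp]
            placement, demoted = _orient_and_place(comp, comp_edges, lengths)
            singles = demoted
        if placement:
            placed = sorted(((sid, placement[sid][0], placement[sid][1])
                             for sid in placement), key=lambda t: (t[2], t[0]))
            oriented = []
            for sid, flip, pos in placed:
                oseq = seqs[sid] if flip == 0 else revcomp(seqs[sid])
                w_or = w_of(sid) if flip == 0 else w_of(sid)[::-1]
                oriented.append((sid, oseq, pos, w_or, flip))
            backbone = _build_backbone([(sid, oseq, pos) for sid, oseq, pos, _, _ in oriented])
            consensus, depth, locs = _vote(backbone,
                                           [(sid, oseq, w_or) for sid, oseq, pos, w_or, _ in oriented])
            mem = []
            seen_reads = set()
            for sid, oseq, pos, w_or, flip in oriented:
                base = locs.get(sid, max(0, pos))
                for rid, off, st in mm_of(sid):
                    if rid in seen_reads:
                        continue
                    seen_reads.add(rid)
                    if flip == 0:
                        new_off = base + off
                        new_st = st
                    else:
                        new_off = base + max(0, lengths[sid] - off - 1)
                        new_st = "-" if st == "+" else "+"
                    new_off = min(max(new_off, 0), max(0, len(consensus) - 1))
                    mem.append((rid, new_off, new_st))
            contigs.append(Contig(id=f"{prefix}{n}", consensus=consensus,
                                  members=mem, depth=depth))
            n += 1
        for sid in singles:
            contigs.append(Contig(id=f"{prefix}{n}", consensus=seqs[sid],
                                  members=list(mm_of(sid)), depth=w_of(sid)))
            n += 1
    return contigs


# ---------------------------------------------------------------------------
# Iterative assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    """Final contigs (>= 2 distinct reads each), singleton read ids, per-cycle counts."""

    contigs: list
    singletons: list
    cycle_contig_counts: list = field(default_factory=list)

    @property
    def read_ids_covered(self) -> set:
        out = set(self.singletons)
        for c in self.contigs:
            out |= {rid for rid, _, _ in c.members}
        return out


def _as_seq_dict(reads) -> dict:
    if hasattr(reads, "items"):
        return dict(reads)
    return {r.id: r.seq for r in reads}


def iterative_assemble(reads, params: OverlapParams = OverlapParams()) -> AssemblyResult:
    """Cluster + assemble, iterated: refinement cycles, then one stricter merge pass.

    Cycle 1 runs on raw reads; later cycles treat the previous cycle's
    contigs plus leftover singletons as the sequence set and re-overlap.
    Membership is traced so every contig lists original read ids, and every
    input read ends up in at least one contig or in the singleton list.
    """
    orig = _as_seq_dict(reads)
    seqs = dict(orig)
    weights = {sid: np.ones(len(s), dtype=np.int64) for sid, s in seqs.items()}
    members_map = {sid: [(sid, 0, "+")] for sid in seqs}
    cycle_counts = []
    total_cycles = params.cycles + (1 if params.merge else 0)
    for cycle in range(1, total_cycles + 1):
        if cycle > params.cycles:       # stricter merge pass
            min_len, min_ident = params.merge_overlap_len, params.merge_identity
        else:
            min_len, min_ident = params.min_overlap_len, params.min_overlap_identity
        overlaps = find_overlaps(seqs, params, min_len=min_len, min_identity=min_ident)
        clusters = precluster(seqs, overlaps)
        produced = []
        merged_any = False
        for cl in clusters:
            if len(cl.members) == 1:
                produced.append(("carry", cl.seed))
                continue
            merged_any = True
            contigs = layout_and_consensus(cl, seqs, params, overlaps, weights,
                                           members_map, prefix=f"a{cycle}_{cl.id}_")
            produced.extend(("contig", c) for c in contigs)
        new_seqs, new_weights, new_members = {}, {}, {}
        seen_membersets = {}
        n_multi = 0
        for kind, item in produced:
            if kind == "carry":
                sid = item
                new_seqs[sid] = seqs[sid]
                new_weights[sid] = weights[sid]
                new_members[sid] = members_map[sid]
                continue
            c = item
            key = frozenset(rid for rid, _, _ in c.members)
            if key in seen_membersets:
                continue
            seen_membersets[key] = c.id
            new_seqs[c.id] = c.consensus
            new_weights[c.id] = np.asarray(c.depth, dtype=np.int64)
            new_members[c.id] = list(c.members)
            if len(key) >= 2:
                n_multi += 1
        seqs, weights, members_map = new_seqs, new_weights, new_members
        cycle_counts.append(n_multi)
        if not merged_any:
            break
    contigs = []
    singletons = []
    for sid, seq in seqs.items():
        mem = members_map[sid]
        distinct = {rid for rid, _, _ in mem}
        if len(distinct) >= 2:
            contigs.append(Contig(id=sid, consensus=seq, members=mem,
                                  depth=weights[sid]))
        else:
            singletons.append(next(iter(distinct)))
    # multi-membership can leave a read both inside a contig and carried alone
    in_contigs = {rid for c in contigs for rid, _, _ in c.members}
    singletons = sorted(set(singletons) - in_contigs)
    missing = set(orig) - in_contigs - set(singletons)
    singletons.extend(sorted(missing))          # defensive: never lose a read
    return AssemblyResult(contigs=contigs, singletons=singletons,
                          cycle_contig_counts=cycle_counts)


def contig_stats(result: AssemblyResult, length_bins: Optional[Iterable[int]] = None,
                 depth_cap: int = 30) -> dict:
    """Length and mean-depth histograms plus the mean contig length.

    Depth values above ``depth_cap`` are pooled into one ``>cap`` bin, the
    way read-depth histograms for normalized libraries are usually drawn.
    """
    lengths = np.array([len(c.consensus) for c in result.contigs])
    depths = np.array([c.mean_depth for c in result.contigs])
    if len(lengths) == 0:
        return {"mean_length": 0.0,
                "length_hist": pd.Series(dtype=int),
                "depth_hist": pd.Series(dtype=int)}
    if length_bins is None:
        top = int(lengths.max()) + 200
        length_bins = list(range(0, top + 200, 200))
    lh = pd.cut(lengths, bins=list(length_bins), right=False).value_counts().sort_index()
    capped = np.minimum(np.ceil(depths).astype(int), depth_cap + 1)
    labels = [str(i) for i in range(1, depth_cap + 1)] + [f">{depth_cap}"]
    dh = pd.Series(0, index=labels, dtype=int)
    for v in capped:
        key = f">{depth_cap}" if v > depth_cap else str(max(v, 1))
        dh[key] += 1
    return {"mean_length": float(lengths.mean()),
            "length_hist": lh,
            "depth_hist": dh}
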