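"""Overlap detection, multi-membership clustering, consensus, iteration."""

import numpy as np
import pytest

from estforge import cluster_assemble as ca
from estforge import simulate as sim
from estforge.align import revcomp
from estforge.seqio import Cluster
from conftest import random_dna


class TestFindOverlaps:
    def test_exact_dovetail_found(self, rng):
        src = random_dna(rng, 500)
        a, b = src[:300], src[200:]
        ovs = ca.find_overlaps({"a": a, "b": b})
        assert len(ovs) == 1
        ov = ovs[0]
        assert {ov.a, ov.b} == {"a", "b"}
        assert ov.length == 100
        assert ov.identity == 1.0

    def test_identical_reads_containment(self, rng):
        s = random_dna(rng, 300)
        ovs = ca.find_overlaps({"a": s, "b": s})
        assert len(ovs) == 1
        assert ovs[0].length == 300
        assert ovs[0].identity == 1.0

    def test_short_overlap_rejected_at_threshold(self, rng):
        src = random_dna(rng, 600)
        a, b = src[:300], src[261:]         # 39 bp shared
        params = ca.OverlapParams(min_overlap_len=40)
        assert ca.find_overlaps({"a": a, "b": b}, params) == []

    def test_reverse_strand_overlap(self, rng):
        src = random_dna(rng, 500)
        a, b = src[:300], revcomp(src[200:])
        ovs = ca.find_overlaps({"a": a, "b": b})
        assert len(ovs) == 1
        assert ovs[0].strand == "-"
        assert ovs[0].length == 100

    def test_no_self_pairs(self, rng):
        s = random_dna(rng, 300)
        assert all(ov.a != ov.b for ov in ca.find_overlaps({"a": s}))


class TestPrecluster:
    def test_tiling_reads_one_cluster(self, rng):
        src = random_dna(rng, 700)
        seqs = {"long": src[:400], "mid": src[150:550], "end": src[300:700]}
        ovs = ca.find_overlaps(seqs)
        clusters = ca.precluster(seqs, ovs)
        assert len(clusters) == 1
        assert clusters[0].members == {"long", "mid", "end"}
        assert clusters[0].seed == "end"    # longest first, length ties by id

    def test_no_overlaps_all_singletons(self, rng):
        seqs = {f"r{i}": random_dna(rng, 200) for i in range(5)}
        clusters = ca.precluster(seqs, [])
        assert len(clusters) == 5
        assert all(len(c.members) == 1 for c in clusters)

    def test_bridging_read_joins_both_clusters(self, rng):
        """A conserved-block read must appear in both paralog clusters."""
        block = random_dna(rng, 150)
        fam1 = random_dna(rng, 250) + block + random_dna(rng, 250)
        fam2 = random_dna(rng, 240) + block + random_dna(rng, 240)
        seqs = {
            "seed1": fam1,                     # longest: seeds cluster 1
            "seed2": fam2,
            "bridge": block,                   # identical in both families
            "f2tail": fam2[400:],              # keeps seed2 unclustered reads
        }
        ovs = ca.find_overlaps(seqs, ca.OverlapParams(min_overlap_len=40,
                                                      min_overlap_identity=0.97))
        clusters = ca.precluster(seqs, ovs)
        n_clusters_with_bridge = sum(1 for c in clusters if "bridge" in c.members)
        assert n_clusters_with_bridge >= 2


class TestLayoutConsensus:
    def test_error_free_tiling_recovers_transcript(self, rng):
        src = random_dna(rng, 1000)
        starts = [0, 180, 360, 540, 720]
        seqs = {f"r{i}": src[s:s + 240] for i, s in enumerate(starts)}
        ovs = ca.find_overlaps(seqs)
        cluster = Cluster(id="cl", seed="r0", members=set(seqs))
        contigs = ca.layout_and_consensus(cluster, seqs, overlaps=ovs)
        assert len(contigs) == 1
        cons = contigs[0].consensus
        assert cons in (src[:starts[-1] + 240], revcomp(src[:starts[-1] + 240]))
        assert len(contigs[0].depth) == len(cons)
        assert {m[0] for m in contigs[0].members} == set(seqs)

    def test_majority_vote_beats_single_error(self, rng):
        src = random_dna(rng, 300)
        mutated = list(src)
        mutated[150] = "A" if src[150] != "A" else "C"
        seqs = {"r0": src, "r1": src, "r2": "".join(mutated)}
        cluster = Cluster(id="cl", seed="r0", members=set(seqs))
        contigs = ca.layout_and_consensus(cluster, seqs)
        assert len(contigs) == 1
        assert contigs[0].consensus == src

    def test_tie_vote_gives_iupac(self, rng):
        src = random_dna(rng, 300)
        mutated = list(src)
        mutated[150] = "A" if src[150] == "C" else "C"
        seqs = {"r0": src, "r1": "".join(mutated)}
        cluster = Cluster(id="cl", seed="r0", members=set(seqs))
        cons = ca.layout_and_consensus(cluster, seqs)[0].consensus
        assert cons[150] in "RYSWKM"        # ambiguity code at the tied column

    def test_disconnected_islands_split(self, rng):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        seqs = {"r0": a, "r1": a[50:250], "r2": b, "r3": b[50:250]}
        cluster = Cluster(id="cl", seed="r0", members=set(seqs))
        contigs = ca.layout_and_consensus(cluster, seqs)
        assert len(contigs) == 2

    def test_depth_counts_reads_per_column(self, rng):
        src = random_dna(rng, 400)
        seqs = {"r0": src[:300], "r1": src[100:400]}
        cluster = Cluster(id="cl", seed="r0", members=set(seqs))
        contig = ca.layout_and_consensus(cluster, seqs)[0]
        assert contig.depth.max() == 2
        assert contig.depth.min() == 1
        assert int((contig.depth == 2).sum()) == pytest.approx(200, abs=5)


class TestIterativeAssemble:
    def test_all_reads_accounted_for(self, rng):
        src = random_dna(rng, 900)
        seqs = {f"r{i}": src[s:s + 250]
                for i, s in enumerate(range(0, 650, 80))}
        seqs["lone"] = random_dna(rng, 200)
        res = ca.iterative_assemble(seqs)
        assert res.read_ids_covered == set(seqs)
        assert "lone" in res.singletons

    def test_fixed_point_for_assembled_input(self, rng):
        src = random_dna(rng, 600)
        seqs = {f"r{i}": src[s:s + 250] for i, s in enumerate((0, 170, 350))}
        res = ca.iterative_assemble(seqs, ca.OverlapParams(cycles=4))
        assert len(res.contigs) == 1
        # later cycles are no-ops once everything is merged
        assert res.cycle_contig_counts[-1] == 0 or len(res.cycle_contig_counts) <= 2

    def test_contig_halves_merge_in_later_cycle(self, rng):
        """Two halves sharing a 60-bp exact overlap fuse during iteration."""
        src = random_dna(rng, 1100)
        half1 = [src[0:280], src[200:480], src[320:580]]
        half2 = [src[520:800], src[700:980], src[850:1100]]
        seqs = {f"a{i}": s for i, s in enumerate(half1)}
        seqs.update({f"b{i}": s for i, s in enumerate(half2)})
        res = ca.iterative_assemble(seqs, ca.OverlapParams(cycles=4))
        assert len(res.contigs) == 1
        assert len(res.contigs[0].consensus) == pytest.approx(1100, abs=20)

    def test_single_cycle_equals_composition(self, rng):
        src = random_dna(rng, 500)
        seqs = {"r0": src[:300], "r1": src[150:450], "r2": random_dna(rng, 200)}
        params = ca.OverlapParams(cycles=1, merge=False)
        res = ca.iterative_assemble(seqs, params)
        ovs = ca.find_overlaps(seqs, params)
        clusters = ca.precluster(seqs, ovs)
        direct = []
        for cl in clusters:
            direct.extend(c for c in ca.layout_and_consensus(cl, seqs, params, ovs)
                          if len(c.members) >= 2)
        assert len(res.contigs) == len(direct)
        assert {c.consensus for c in res.contigs} == {c.consensus for c in direct}

    def test_raising_identity_never_reduces_singletons(self, rng):
        cfg = sim.SimConfig(seed=21, n_genes=6, n_reads=120, adapter_prob=0,
                            polyA_prob=0, transcript_len_range=(400, 800),
                            ssr_insert_prob=0, retro_insert_prob=0)
        tr, _ = sim.make_transcriptome(cfg)
        w = np.ones(len(tr)) / len(tr)
        reads, _ = sim.make_reads(tr, w, cfg, "seed")
        seqs = {r.id: r.seq for r in reads}
        counts = []
        for ident in (0.90, 0.97, 0.999):
            params = ca.OverlapParams(min_overlap_identity=ident, cycles=1,
                                      merge=False)
            counts.append(len(ca.iterative_assemble(seqs, params).singletons))
        assert counts[0] <= counts[1] <= counts[2]


class TestContigStats:
    def test_mean_length(self, rng):
        src = [random_dna(rng, n) for n in (400, 600, 600)]
        contigs = []
        for i, s in enumerate(src):
            seqs = {f"r{i}a": s, f"r{i}b": s}
            cl = Cluster(id=f"c{i}", seed=f"r{i}a", members=set(seqs))
            contigs.extend(ca.layout_and_consensus(cl, seqs))
        res = ca.AssemblyResult(contigs=contigs, singletons=[])
        stats = ca.contig_stats(res)
        assert stats["mean_length"] == pytest.approx(533.3, abs=0.5)

    def test_depth_above_cap_pooled(self, rng):
        s = random_dna(rng, 200)
        seqs = {f"r{i}": s for i in range(35)}
        cl = Cluster(id="c", seed="r0", members=set(seqs))
        contig = ca.layout_and_consensus(cl, seqs)[0]
        res = ca.AssemblyResult(contigs=[contig], singletons=[])
        stats = ca.contig_stats(res, depth_cap=30)
        assert stats["depth_hist"][">30"] == 1

    def test_empty_result(self):
        stats = ca.contig_stats(ca.AssemblyResult(contigs=[], singletons=[]))
        assert stats["mean_length"] == 0.0
        assert len(stats["length_hist"]) == 0
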