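"""Shredding, fragment mapping, RPKM arithmetic, filters, UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from estforge import quantify
from estforge.align import revcomp
from estforge.seqio import Read
from conftest import random_dna


def read_of(seq, rid="r", lib="seed"):
    return Read(id=rid, seq=seq, library=lib)


class TestShred:
    @pytest.mark.parametrize("length,expected", [(367, 9), (39, 0), (80, 2), (40, 1)])
    def test_fragment_counts(self, length, expected, rng):
        frags = quantify.shred(read_of(random_dna(rng, length)))
        assert len(frags) == expected

    def test_offsets_and_ids(self, rng):
        seq = random_dna(rng, 85)
        frags = quantify.shred(read_of(seq, rid="x"))
        assert [f.seq for f in frags] == [seq[0:40], seq[40:80]]
        assert [f.id for f in frags] == ["x/0", "x/1"]

    def test_pure_function(self, rng):
        r = read_of(random_dna(rng, 200))
        assert [f.seq for f in quantify.shred(r)] == [f.seq for f in quantify.shred(r)]


class TestMapFragments:
    def test_exact_fragment_counted(self, rng):
        contig = random_dna(rng, 300)
        frags = [quantify.Fragment("r", 0, contig[50:90], "seed")]
        res = quantify.map_fragments(frags, {"c1": contig})
        assert res.counts.at["c1", "seed"] == 1

    def test_reverse_strand_fragment_counted(self, rng):
        contig = random_dna(rng, 300)
        frags = [quantify.Fragment("r", 0, revcomp(contig[50:90]), "seed")]
        res = quantify.map_fragments(frags, {"c1": contig})
        assert res.counts.at["c1", "seed"] == 1

    def test_three_mismatches_unmapped(self, rng):
        contig = random_dna(rng, 300)
        frag = list(contig[50:90])
        for i in (5, 15, 25):
            frag[i] = "A" if frag[i] != "A" else "C"
        res = quantify.map_fragments([quantify.Fragment("r", 0, "".join(frag), "seed")],
                                     {"c1": contig})
        assert res.unmapped["seed"] == 1
        assert res.counts.at["c1", "seed"] == 0

    def test_two_mismatches_mapped(self, rng):
        contig = random_dna(rng, 300)
        frag = list(contig[50:90])
        for i in (5, 25):
            frag[i] = "A" if frag[i] != "A" else "C"
        res = quantify.map_fragments([quantify.Fragment("r", 0, "".join(frag), "seed")],
                                     {"c1": contig})
        assert res.counts.at["c1", "seed"] == 1

    def test_tie_goes_to_smallest_contig_id(self, rng):
        contig = random_dna(rng, 200)
        frags = [quantify.Fragment("r", 0, contig[20:60], "seed")]
        res = quantify.map_fragments(frags, {"b": contig, "a": contig})
        assert res.counts.at["a", "seed"] == 1
        assert res.counts.at["b", "seed"] == 0


class TestRpkm:
    def test_worked_example(self):
        assert quantify.rpkm(25, 1000, 25_000_000) == 1.0

    def test_zero_count(self):
        assert quantify.rpkm(0, 500, 1_000_000) == 0.0

    def test_formula(self):
        assert quantify.rpkm(100, 500, 1_000_000) == pytest.approx(200.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            quantify.rpkm(1, 500, 0)


def matrix_from(counts, lengths, totals):
    mapping = quantify.MappingResult(
        counts=pd.DataFrame(counts).T,
        total_mapped=totals, total_fragments=dict(totals),
        unmapped={k: 0 for k in totals})
    return quantify.build_matrix(mapping, lengths)


class TestBuildMatrix:
    LIBS = ("seed", "seedling", "tiller", "flower")

    def profile(self, rpkms, length=1000, total=1_000_000):
        # counts that produce the requested RPKM values exactly
        counts = {lib: int(r * length * total / 1e9) for lib, r in
                  zip(self.LIBS, rpkms)}
        return matrix_from({"c1": counts}, {"c1": length}, {lib: total for lib in self.LIBS})

    def test_low_everywhere_not_detected(self):
        m = self.profile((0.5, 0.8, 0.2, 0.9))
        assert "c1" not in m.detected.index

    def test_single_high_library_enters_clustering_subset(self):
        m = self.profile((12, 0, 0, 0))
        assert "c1" in m.clustering_subset.index

    def test_nine_everywhere_detected_but_not_clustered(self):
        m = self.profile((9, 9, 9, 9))
        assert "c1" in m.detected.index
        assert "c1" not in m.clustering_subset.index

    def test_conservation_and_scale_invariance(self, rng):
        contigs = {f"c{i}": random_dna(rng, int(rng.integers(200, 1200)))
                   for i in range(20)}
        reads = []
        cseqs = list(contigs.values())
        for i in range(300):
            src = cseqs[int(rng.integers(0, len(cseqs)))]
            n = int(rng.integers(80, min(360, len(src))))
            s = int(rng.integers(0, len(src) - n + 1))
            reads.append(read_of(src[s:s + n], rid=f"r{i}",
                                 lib=self.LIBS[i % 4]))
        frags = quantify.shred_collection(reads)
        mapping = quantify.map_fragments(frags, contigs, libraries=list(self.LIBS))
        # conservation: column sums equal per-library totals
        for lib in self.LIBS:
            assert int(mapping.counts[lib].sum()) == mapping.total_mapped[lib]
        lengths = {c: len(s) for c, s in contigs.items()}
        m1 = quantify.build_matrix(mapping, lengths)
        for lib in self.LIBS:
            total = mapping.total_mapped[lib]
            if total:
                back = (m1.rpkm[lib] * pd.Series(lengths) * total / 1e9).sum()
                assert back == pytest.approx(total, rel=1e-9)
        # scale invariance: count and total x10 leaves RPKM unchanged
        scaled = quantify.MappingResult(
            counts=mapping.counts * 10,
            total_mapped={k: v * 10 for k, v in mapping.total_mapped.items()},
            total_fragments=mapping.total_fragments, unmapped=mapping.unmapped)
        m2 = quantify.build_matrix(scaled, lengths)
        assert np.allclose(m1.rpkm.values, m2.rpkm.values)


class TestLog2Transform:
    def test_values(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 15.0]})
        out = quantify.log2_transform(df, offset=1.0)
        assert list(out["a"]) == pytest.approx([0.0, 1.0, 4.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quantify.log2_transform(pd.DataFrame({"a": [-1.0]}))


class TestAverageLinkage:
    def test_identical_profiles_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                          index=["a", "b", "c"])
        Z, labels = quantify.average_linkage_cluster(df)
        assert Z[0, 2] == 0.0
        assert {labels[int(Z[0, 0])], labels[int(Z[0, 1])]} == {"a", "b"}

    def test_hand_computed_upgma_on_line(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]], index=list("abcd"))
        Z, labels = quantify.average_linkage_cluster(df)
        first_two = [{labels[int(Z[i, 0])] if Z[i, 0] < 4 else None,
                      labels[int(Z[i, 1])] if Z[i, 1] < 4 else None}
                     for i in range(2)]
        assert {"a", "b"} in first_two and {"c", "d"} in first_two
        assert Z[0, 2] == 1.0 and Z[1, 2] == 1.0
        assert Z[2, 2] == pytest.approx(10.0)     # mean inter-cluster distance

    def test_permutation_invariant_heights(self, rng):
        data = rng.normal(size=(8, 4))
        df = pd.DataFrame(data, index=[f"i{k}" for k in range(8)])
        Z1, _ = quantify.average_linkage_cluster(df)
        perm = rng.permutation(8)
        Z2, _ = quantify.average_linkage_cluster(df.iloc[perm])
        assert np.allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]))

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            quantify.average_linkage_cluster(pd.DataFrame([[1.0]], index=["a"]))

    def test_newick_round_trip(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]], index=list("abcd"))
        Z, labels = quantify.average_linkage_cluster(df)
        nwk = quantify.linkage_to_newick(Z, labels)
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]
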