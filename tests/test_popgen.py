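import math

import numpy as np
import pytest
from _oracles import (
    balanced_tn93_pair,
    hd_by_pair_enumeration,
    pi_by_pair_loop,
    tn93_closed_form,
)
from conftest import aln, random_seq
from hypothesis import given, settings
from hypothesis import strategies as st

from panplastome.errors import InputError, NoInformativeSitesError, SaturationError
from panplastome.popgen import (
    DistanceMatrix,
    Haplotype,
    HaplotypeSet,
    cluster_diversity,
    collapse_haplotypes,
    haplotype_diversity,
    nj_tree,
    nucleotide_diversity,
    p_distance,
    pairwise_distance_matrix,
    pairwise_fst,
    pca_coordinates,
    tn93_distance,
)


def hapset(counts):
    return HaplotypeSet(
        [Haplotype(f"h{i+1}", f"X{i}", [f"s{i}_{j}" for j in range(c)])
         for i, c in enumerate(counts)],
        np.arange(1),
    )


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        a = aln(("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT"))
        hs = collapse_haplotypes(a)
        assert len(hs.haplotypes) == 1
        assert hs.haplotypes[0].members == ["a", "b", "c"]

    def test_gap_column_eliminated_before_comparison(self):
        # a and b differ only where c holds a gap -> all collapse together
        a = aln(("a", "ACGT"), ("b", "AGGT"), ("c", "A-GT"))
        hs = collapse_haplotypes(a)
        assert len(hs.haplotypes) == 1
        assert hs.retained_columns.tolist() == [0, 2, 3]

    def test_all_distinct(self):
        a = aln(("a", "AAAA"), ("b", "AAAC"), ("c", "AACA"), ("d", "ACAA"))
        assert len(collapse_haplotypes(a).haplotypes) == 4

    def test_no_informative_sites(self):
        a = aln(("a", "A-"), ("b", "-A"))
        with pytest.raises(NoInformativeSitesError):
            collapse_haplotypes(a)

    def test_first_occurrence_ids(self):
        a = aln(("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA"))
        hs = collapse_haplotypes(a)
        assert hs.membership() == {"a": "h1", "b": "h2", "c": "h1"}


class TestHd:
    def test_single_haplotype_zero(self):
        assert haplotype_diversity(hapset([3])) == 0.0

    def test_all_distinct_is_one(self):
        assert haplotype_diversity(hapset([1, 1, 1, 1])) == 1.0

    def test_5_3_2_matches_pair_enumeration(self):
        expected = hd_by_pair_enumeration([5, 3, 2])
        assert expected == pytest.approx(31 / 45)
        assert haplotype_diversity(hapset([5, 3, 2])) == pytest.approx(expected)

    def test_n_below_two_rejected(self):
        with pytest.raises(InputError):
            haplotype_diversity(hapset([1]))

    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=6)
           .filter(lambda c: sum(c) >= 2))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, counts):
        assert haplotype_diversity(hapset(counts)) == pytest.approx(
            hd_by_pair_enumeration(counts), abs=1e-12
        )


class TestPi:
    def test_one_difference_in_ten(self):
        a = aln(("a", "ACGTACGTAC"), ("b", "ACGTACGTAT"))
        assert nucleotide_diversity(a) == pytest.approx(0.1)

    def test_identical_zero(self):
        a = aln(("a", "ACGT"), ("b", "ACGT"))
        assert nucleotide_diversity(a) == 0.0

    def test_three_sequences_mean_of_pairs(self):
        base = "A" * 100
        s1 = base
        s2 = "C" + base[1:]  # d(s1,s2)=1
        s3 = "G" + "G" + base[2:]  # d(s1,s3)=2, d(s2,s3)=3? -> check by oracle
        a = aln(("a", s1), ("b", s2), ("c", s3))
        assert nucleotide_diversity(a) == pytest.approx(pi_by_pair_loop([s1, s2, s3]))

    def test_matches_pair_loop_on_random_alignments(self, rng):
        for _ in range(5):
            rows = [random_seq(rng, 200) for _ in range(10)]
            a = aln(*[(f"s{i}", r) for i, r in enumerate(rows)])
            assert nucleotide_diversity(a) == pytest.approx(
                pi_by_pair_loop(rows), abs=1e-12
            )

    def test_relabeling_invariance(self, rng):
        rows = [random_seq(rng, 100) for _ in range(6)]
        a = aln(*[(f"s{i}", r) for i, r in enumerate(rows)])
        b = aln(*[(f"s{i}", r) for i, r in enumerate(reversed(rows))])
        assert nucleotide_diversity(a) == pytest.approx(nucleotide_diversity(b))

    def test_no_columns_error(self):
        a = aln(("a", "--"), ("b", "AA"))
        with pytest.raises(NoInformativeSitesError):
            nucleotide_diversity(a)


class TestTN93:
    def test_identical_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            tn93_distance("A" * 50 + "C" * 50, "G" * 50 + "C" * 50)

    def test_against_closed_form_oracle(self):
        # 100 sites scaled x12: 5% A<->G, 5% C<->T, 10% transversions
        sa, sb = balanced_tn93_pair(p1_sites=60, p2_sites=60, q_sites=120,
                                    repeats=300)
        expected = tn93_closed_form(
            {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
            p1=0.05, p2=0.05, q=0.10,
        )
        assert tn93_distance(sa, sb) == pytest.approx(expected, abs=1e-12)

    def test_at_least_p_distance(self, rng):
        for _ in range(10):
            a, b = random_seq(rng, 400), random_seq(rng, 400)
            try:
                assert tn93_distance(a, b) >= p_distance(a, b) - 1e-12
            except SaturationError:
                pass

    def test_jc_limit(self):
        # equal pooled frequencies with P1 = P2 = Q/4 collapses to Jukes-Cantor
        sa, sb = balanced_tn93_pair(p1_sites=12, p2_sites=12, q_sites=48,
                                    repeats=300)
        p = p_distance(sa, sb)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_distance(sa, sb) == pytest.approx(jc, abs=1e-9)

    def test_zero_purine_fallback(self):
        with pytest.warns(UserWarning, match="p-distance"):
            d = tn93_distance("CCCCTTTT", "CCCCTTCC")
        assert d == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        assert tn93_distance("ACGTN", "ACGTA") == 0.0


class TestFst:
    def test_fixed_disjoint_clusters_one(self):
        a = aln(("a1", "AAAA"), ("a2", "AAAA"), ("b1", "TTTT"), ("b2", "TTTT"))
        assert pairwise_fst(a, ["a1", "a2"], ["b1", "b2"], model="p") == 1.0

    def test_identical_clusters_nan(self):
        a = aln(("a1", "ACGT"), ("a2", "ACGT"), ("b1", "ACGT"), ("b2", "ACGT"))
        with pytest.warns(UserWarning):  # no SNV columns
            result = pairwise_fst(a, ["a1", "a2"], ["b1", "b2"], model="p")
        assert math.isnan(result)

    def test_constructed_means_match_arithmetic(self):
        base = "A" * 100
        a1 = base
        a2 = "C" + base[1:]
        b1 = base[:10] + "GG" + base[12:]
        b2 = "A" + "T" + base[2:10] + "GG" + base[12:]
        a = aln(("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2))
        # oracle: raw mismatch counts (denominators cancel in the ratio)
        within = (1 + 1) / 2.0
        between = (2 + 3 + 3 + 4) / 4.0
        expected = 1.0 - within / between
        got = pairwise_fst(a, ["a1", "a2"], ["b1", "b2"], model="p")
        assert got == pytest.approx(expected)

    def test_small_cluster_rejected(self):
        a = aln(("a1", "ACGT"), ("b1", "ACGA"), ("b2", "ACGA"))
        with pytest.raises(InputError):
            pairwise_fst(a, ["a1"], ["b1", "b2"])


class TestPCA:
    def test_two_groups_separate_on_first_component(self):
        rows = [("g1_%d" % i, "AAAA") for i in range(3)] + [
            ("g2_%d" % i, "TTTT") for i in range(3)
        ]
        a = aln(*rows)
        sub, _ = __import__("panplastome.variants", fromlist=["snv_matrix"]).snv_matrix(a)
        coords, evr = pca_coordinates(sub)
        first = coords[:, 0]
        assert np.allclose(first[:3], first[0])
        assert np.allclose(first[3:], first[3])
        assert abs(first[0] - first[3]) > 0.1

    def test_centering_and_evr(self, rng):
        sub = np.array(
            [list(random_seq(rng, 30)) for _ in range(8)], dtype="S1"
        )
        try:
            coords, evr = pca_coordinates(sub)
        except InputError:
            pytest.skip("degenerate random matrix")
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            pca_coordinates(np.array([[b"A"], [b"C"]], dtype="S1"))


class TestNJ:
    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        mat = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, mat))
        dists = {t.name: t.length for t in tree.tips()}
        assert dists["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert dists["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert dists["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):3,C:4,D:5)
        labels = ["A", "B", "C", "D"]
        d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
             ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        mat = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    mat[i, j] = mat[j, i] = d[(x, y)]
        tree = nj_tree(DistanceMatrix(labels, mat))
        td = tree.tip_tip_distances()
        for (x, y), v in d.items():
            assert td[x, y] == pytest.approx(v, abs=1e-9)

    def test_ultrametric_matches_single_linkage_groups(self):
        # heights: (A,B) at 1, ((A,B),C) at 2, all at 4 with (D,E) at 1
        labels = ["A", "B", "C", "D", "E"]
        h = {("A", "B"): 2, ("A", "C"): 4, ("B", "C"): 4,
             ("D", "E"): 2}
        mat = np.full((5, 5), 8.0)
        np.fill_diagonal(mat, 0.0)
        for (x, y), v in h.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, mat))
        # single-linkage on this matrix groups {A,B,C} and {D,E}
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        sl = fcluster(linkage(squareform(mat), "single"), 2, "maxclust")
        groups = {}
        for lbl, c in zip(labels, sl):
            groups.setdefault(c, set()).add(lbl)
        expected_bipartition = {frozenset(g) for g in groups.values()}
        # the NJ tree must contain a split inducing the same bipartition
        splits = set()
        for node in tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            splits.add(tips)
            splits.add(frozenset(labels) - tips)
        assert expected_bipartition <= splits

    def test_asymmetric_rejected(self):
        mat = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(InputError):
            DistanceMatrix(["a", "b", "c"], mat)

    def test_random_additive_recovery(self, rng):
        from skbio import TreeNode

        for trial in range(10):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            nodes = [TreeNode(name=lbl) for lbl in labels]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                a, b = nodes[j], nodes[i]
                a.length = float(rng.uniform(0.1, 1.0))
                b.length = float(rng.uniform(0.1, 1.0))
                merged = TreeNode(children=[b, a])
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                nodes.append(merged)
            truth = nodes[0]
            td = truth.tip_tip_distances(endpoints=labels)
            mat = np.asarray(td.data)
            recovered = nj_tree(DistanceMatrix(list(td.ids), mat))
            rd = recovered.tip_tip_distances(endpoints=list(td.ids))
            assert np.allclose(np.asarray(rd.data), mat, atol=1e-9)


class TestClusterDiversity:
    def test_shared_frame(self, small_simulation):
        sim = small_simulation
        clusters = {}
        for s, c in sim.cluster_labels.items():
            clusters.setdefault(c, []).append(s)
        stats = cluster_diversity(sim.alignment, clusters)
        # cluster2 was simulated without extra within-cluster SNVs
        assert stats["cluster2"].h == 1
        assert stats["cluster2"].hd == 0.0
        assert stats["cluster1"].hd > stats["cluster2"].hd
        assert stats["cluster1"].pi > stats["cluster2"].pi


def test_pairwise_distance_matrix_symmetry(rng):
    rows = np.array([list(random_seq(rng, 100)) for _ in range(5)], dtype="S1")
    dm = pairwise_distance_matrix(rows, [f"s{i}" for i in range(5)], model="p")
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.all(np.diag(dm.matrix) == 0)
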