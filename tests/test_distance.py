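import numpy as np
import pandas as pd
import pytest

from drugatlas import (
    DistanceMatrix,
    ResponseMatrix,
    cluster_drugs,
    cophenetic_correlation,
    cophenetic_distance,
    cosine_dissimilarity,
    pathway_distance_sets,
    target_distance,
)
from conftest import random_distance_matrix, random_tree


def brute_force_cophenetic(tree):
    """Independent oracle: union-find over the merge sequence.

    Two leaves' cophenetic distance is the height of the merge that first
    puts them in the same cluster.
    """
    n = tree.n_leaves
    out = np.zeros((n, n))
    next_id = n
    sets = {i: {i} for i in range(n)}
    for a, b, h, _ in tree.Z:
        sa, sb = sets.pop(int(a)), sets.pop(int(b))
        for i in sa:
            for j in sb:
                out[i, j] = out[j, i] = h
        sets[next_id] = sa | sb
        next_id += 1
    return pd.DataFrame(out, index=tree.labels, columns=tree.labels)


def make_response(arr, drugs, lines):
    vals = pd.DataFrame(np.asarray(arr, float), index=drugs, columns=lines)
    return ResponseMatrix(values=vals, value_kind="auc",
                          tissue_of={c: "t" for c in lines})


class TestCosineDissimilarity:
    def test_identical_vectors_zero(self):
        m = make_response([[0.2, 0.4, 0.6], [0.2, 0.4, 0.6]],
                          ["dA", "dB"], ["c1", "c2", "c3"])
        d = cosine_dissimilarity(m, min_overlap=3)
        assert d.matrix.loc["dA", "dB"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_inner_product(self):
        # effect vectors (1,0,1) and (1,1,0): cos = 1/2 -> distance 0.5
        m = make_response([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
                          ["dA", "dB"], ["c1", "c2", "c3"])
        d = cosine_dissimilarity(m, min_overlap=3)
        assert d.matrix.loc["dA", "dB"] == pytest.approx(0.5)

    def test_orthogonal_vectors_one(self):
        m = make_response([[0.0, 1.0], [1.0, 0.0]], ["dA", "dB"], ["c1", "c2"])
        d = cosine_dissimilarity(m, min_overlap=2)
        assert d.matrix.loc["dA", "dB"] == pytest.approx(1.0)

    def test_insufficient_overlap_missing_with_warning(self):
        arr = np.array([[0.1, 0.2, np.nan, np.nan],
                        [np.nan, np.nan, 0.3, 0.4]])
        m = make_response(arr, ["dA", "dB"], ["c1", "c2", "c3", "c4"])
        with pytest.warns(UserWarning, match="min_overlap"):
            d = cosine_dissimilarity(m, min_overlap=2)
        assert np.isnan(d.matrix.loc["dA", "dB"])

    def test_zero_effect_vector_rejected(self):
        m = make_response([[1.0, 1.0], [0.1, 0.2]], ["dA", "dB"], ["c1", "c2"])
        with pytest.raises(ValueError, match="all-zero"):
            cosine_dissimilarity(m, min_overlap=2)


class TestClusterDrugs:
    def test_two_drugs_merge_at_distance(self):
        d = DistanceMatrix(pd.DataFrame([[0, 0.4], [0.4, 0]],
                                        index=["a", "b"], columns=["a", "b"]))
        tree = cluster_drugs(d, method="average")
        assert tree.root_height == pytest.approx(0.4)

    def test_closest_pair_merges_first(self):
        m = pd.DataFrame([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = cluster_drugs(DistanceMatrix(m), method="average")
        first_groups = tree.cut(0.5)
        assert first_groups["A"] == first_groups["B"] != first_groups["C"]

    def test_permutation_invariant_merge_set(self):
        d = random_distance_matrix(8, 5)
        perm = [3, 1, 7, 0, 2, 6, 5, 4]
        labels = [d.items[i] for i in perm]
        d2 = DistanceMatrix(d.matrix.loc[labels, labels], d.metric)
        t1 = cluster_drugs(d, "average")
        t2 = cluster_drugs(d2, "average")
        c1 = cophenetic_distance(t1).matrix
        c2 = cophenetic_distance(t2).matrix.loc[c1.index, c1.columns]
        pd.testing.assert_frame_equal(c1, c2)

    def test_single_item_rejected(self):
        d = DistanceMatrix(pd.DataFrame([[0.0]], index=["a"], columns=["a"]))
        with pytest.raises(ValueError, match="two items"):
            cluster_drugs(d)

    def test_missing_entries_imputed_by_median(self, caplog):
        m = random_distance_matrix(5, 1).matrix.copy()
        m.iloc[0, 3] = m.iloc[3, 0] = np.nan
        with caplog.at_level("WARNING", logger="drugatlas"):
            cluster_drugs(DistanceMatrix(m), "average")
        assert any("imputing" in r.message for r in caplog.records)


class TestCopheneticDistance:
    def test_zero_diagonal(self):
        t = random_tree(6, 2)
        d = cophenetic_distance(t)
        assert np.all(np.diag(d.matrix.to_numpy()) == 0)

    def test_three_leaf_hand_tree(self):
        from drugatlas.distance import ClusterTree
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [3.0, 2.0, 2.0, 3.0]])
        tree = ClusterTree(["A", "B", "C"], Z, "average")
        d = cophenetic_distance(tree, normalize=False).matrix
        assert d.loc["A", "B"] == 1.0
        assert d.loc["A", "C"] == 2.0 and d.loc["B", "C"] == 2.0

    def test_normalized_root_pair_is_one(self):
        t = random_tree(10, 3)
        d = cophenetic_distance(t, normalize=True)
        assert d.matrix.to_numpy().max() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_union_find_oracle(self, seed):
        t = random_tree(int(np.random.default_rng(seed).integers(3, 20)), seed)
        got = cophenetic_distance(t, normalize=False).matrix
        exp = brute_force_cophenetic(t)
        np.testing.assert_allclose(got.to_numpy(), exp.to_numpy(), atol=1e-12)

    def test_ultrametric_on_random_tree(self):
        M = cophenetic_distance(random_tree(12, 9)).matrix.to_numpy()
        n = len(M)
        for j in range(n):
            assert np.all(M <= np.maximum.outer(M[:, j], M[j, :]) + 1e-12)

    def test_average_linkage_reproduces_ultrametric_input(self):
        t = random_tree(10, 4)
        ultra = cophenetic_distance(t, normalize=False)
        t2 = cluster_drugs(ultra, method="average")
        back = cophenetic_distance(t2, normalize=False).matrix
        np.testing.assert_allclose(
            back.to_numpy(),
            ultra.matrix.loc[back.index, back.columns].to_numpy(), atol=1e-10)


class TestCopheneticCorrelation:
    def test_perfect_tree_gives_one(self):
        t = random_tree(8, 7)
        ultra = cophenetic_distance(t, normalize=False)
        rep = cophenetic_correlation(ultra, t)
        assert rep.c == pytest.approx(1.0, abs=1e-12)

    def test_formula_matches_pearson_routine(self):
        d = random_distance_matrix(9, 13)
        t = cluster_drugs(d, "average")
        rep = cophenetic_correlation(d, t)
        expected = np.corrcoef(rep.x_pairs, rep.t_pairs)[0, 1]
        assert rep.c == pytest.approx(expected, abs=1e-12)

    def test_anti_ordered_negative(self):
        from drugatlas.distance import ClusterTree
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [3.0, 2.0, 2.0, 3.0]])
        tree = ClusterTree(["A", "B", "C"], Z, "average")
        # input distances reversed relative to the tree
        m = pd.DataFrame([[0, 2.0, 1.0], [2.0, 0, 1.0], [1.0, 1.0, 0]],
                         index=["A", "B", "C"], columns=["A", "B", "C"])
        rep = cophenetic_correlation(DistanceMatrix(m), tree)
        assert rep.c < 0

    def test_constant_tree_distances_warns_nan(self):
        from drugatlas.distance import ClusterTree
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [3.0, 2.0, 1.0, 3.0]])
        tree = ClusterTree(["A", "B", "C"], Z, "average")
        d = random_distance_matrix(3, 0, labels=["A", "B", "C"])
        with pytest.warns(UserWarning, match="constant"):
            rep = cophenetic_correlation(d, tree)
        assert np.isnan(rep.c)


class TestTargetAndPathwayDistances:
    def test_singleton_targets_equal_drug_distance(self, toy_annotation):
        t = random_tree(3, 1)
        t.labels = ["dA", "dB", "dC"]
        coph = cophenetic_distance(t).matrix
        from drugatlas import Annotation
        ann = Annotation(targets_of={"dA": {"EGFR"}, "dB": {"KRAS"}})
        td = target_distance(t, ann).matrix
        assert td.loc["EGFR", "KRAS"] == pytest.approx(coph.loc["dA", "dB"])

    def test_mean_over_cross_pairs(self):
        from drugatlas import Annotation
        from drugatlas.distance import ClusterTree
        # caterpillar with known heights: d(A,C)=2, d(B,C)=2? build explicit
        Z = np.array([[0.0, 1.0, 0.4, 2.0], [3.0, 2.0, 0.8, 3.0]])
        tree = ClusterTree(["A", "B", "C"], Z, "average")
        ann = Annotation(targets_of={"A": {"u"}, "B": {"u"}, "C": {"v"}})
        td = target_distance(tree, ann, normalize=False).matrix
        # cross pairs (A,C) and (B,C) both at height 0.8
        assert td.loc["u", "v"] == pytest.approx(0.8)
        assert td.loc["u", "u"] == pytest.approx(0.4)  # within-target pair

    def test_single_drug_two_targets_missing(self):
        from drugatlas import Annotation
        t = random_tree(3, 2, "average")
        ann = Annotation(targets_of={t.labels[0]: {"u", "v"}})
        td = target_distance(t, ann).matrix
        assert np.isnan(td.loc["u", "v"])

    def test_pathway_counts_and_exclusion(self):
        from drugatlas import Annotation
        t = random_tree(5, 6)
        a, b, c, d, e = t.labels
        ann = Annotation(
            pathway_of={a: "p1", b: "p1", c: "p2", d: "p2", e: "p1"},
            cross_reactive={e},
        )
        within, between = pathway_distance_sets(t, ann)
        assert len(within) == 2 and len(between) == 4  # e excluded

    def test_single_group_has_no_between(self):
        from drugatlas import Annotation
        t = random_tree(4, 8)
        ann = Annotation(pathway_of={l: "p" for l in t.labels})
        within, between = pathway_distance_sets(t, ann)
        assert between == [] and len(within) == 6
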