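import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from flowerweb import (
    PresenceTable,
    bootstrap_support,
    jaccard_classic,
    jaccard_distance_matrix,
    shannon_diversity,
    upgma,
)


class TestShannon:
    @pytest.mark.parametrize("k", [1, 4, 8, 75])
    def test_equal_weights_give_log_richness(self, k):
        assert shannon_diversity(np.ones(k)) == pytest.approx(np.log(k), abs=1e-12)

    def test_zero_weights_ignored_and_scale_invariant(self):
        w = np.array([2.0, 0.0, 6.0, 2.0])
        assert shannon_diversity(w) == pytest.approx(shannon_diversity(10 * w))
        assert shannon_diversity(w) == pytest.approx(shannon_diversity([2, 6, 2]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0.0, 0.0])

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_uniform_maximises(self, weights):
        h = shannon_diversity(weights)
        assert h <= np.log(len(weights)) + 1e-9


class TestJaccard:
    def test_identity_disjoint_and_formula(self):
        assert jaccard_classic({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_classic({"a"}, {"b"}) == 0.0
        assert jaccard_classic({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(0.4)

    def test_two_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard_classic(set(), set())

    def test_distance_matrix_properties(self):
        P = PresenceTable(
            ("A", "B", "C"),
            ("s1", "s2", "s3", "s4"),
            np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]]),
        )
        D = jaccard_distance_matrix(P)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert D.loc["A", "B"] == 0.0  # identical assemblages
        assert D.loc["A", "C"] == 1.0  # disjoint assemblages


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        # d(A,B)=0.2, d(A,C)=0.6, d(B,C)=0.8: merge {A,B} at 0.1, root at 0.35
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        tree = upgma(D, ["A", "B", "C"])
        (a, b, h1), (c, d, h2) = tree.merges
        assert {a, b} == {0, 1} and h1 == pytest.approx(0.1)
        assert h2 == pytest.approx(0.35)

    def test_two_leaves(self):
        tree = upgma(np.array([[0, 0.4], [0.4, 0]]), ["X", "Y"])
        assert tree.merges == [(0, 1, 0.2)]

    def test_heights_monotone_and_match_scipy(self):
        rng = np.random.default_rng(7)
        pts = rng.random((6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = upgma(D, list("ABCDEF"))
        heights = [h for _, _, h in tree.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        # independent oracle: scipy average linkage (heights are full cluster
        # distances, ours are half)
        Z = linkage(squareform(D), method="average")
        assert np.allclose(sorted(h * 2 for h in heights), sorted(Z[:, 2]))

    def test_scipy_agrees_on_cluster_composition(self):
        rng = np.random.default_rng(11)
        pts = rng.random((7, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = list("ABCDEFG")
        tree = upgma(D, labels)
        Z = linkage(squareform(D), method="average")
        ours = set(tree.internal_clusters().values())
        sets = {i: frozenset([labels[i]]) for i in range(7)}
        theirs = set()
        for k, (a, b, _h, _n) in enumerate(Z):
            sets[7 + k] = sets[int(a)] | sets[int(b)]
            theirs.add(sets[7 + k])
        assert ours == theirs

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0, 1], [2, 0]]), ["A", "B"])

    def test_tie_break_is_lexicographic(self):
        # all distances equal: first merge must be the lexicographically
        # smallest pair of labels
        D = np.full((4, 4), 0.5)
        np.fill_diagonal(D, 0)
        tree = upgma(D, ["d", "c", "b", "a"])
        a, b, _ = tree.merges[0]
        assert {tree.leaf_labels[a], tree.leaf_labels[b]} == {"a", "b"}


class TestBootstrap:
    @pytest.fixture
    def split_table(self):
        # two habitat groups sharing no species: resampling can never mix them
        pres = np.zeros((4, 10), dtype=int)
        pres[0, :3] = pres[1, :3] = 1
        pres[1, 3] = 1
        pres[2, 4:8] = pres[3, 4:8] = 1
        pres[3, 8] = 1
        return PresenceTable(("A", "B", "C", "D"), tuple(f"s{i}" for i in range(10)), pres)

    def test_disjoint_groups_get_full_support(self, split_table):
        tree = bootstrap_support(split_table, n_rep=300, seed=1)
        support = {tree.clusters()[i]: s for i, s in tree.support.items()}
        assert support[frozenset("AB")] == 100.0
        assert support[frozenset("CD")] == 100.0
        assert support[frozenset("ABCD")] == 100.0  # root by definition

    def test_support_bounded_and_deterministic(self, split_table):
        t1 = bootstrap_support(split_table, n_rep=50, seed=9)
        t2 = bootstrap_support(split_table, n_rep=50, seed=9)
        assert t1.support == t2.support
        assert all(0 <= v <= 100 for v in t1.support.values())

    def test_single_replicate_runs(self, split_table):
        tree = bootstrap_support(split_table, n_rep=1, seed=0)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_newick_contains_support_and_leaves(self, split_table):
        tree = bootstrap_support(split_table, n_rep=20, seed=0)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "ABCD":
            assert leaf in nwk
        assert "100" in nwk
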