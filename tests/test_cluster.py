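import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import gsasynth as gs
from gsasynth.cluster import Partition, asw_label
from gsasynth.errors import ValidationError

LINKAGES = ("single", "complete", "average")


def three_item_matrix():
    d = np.full((3, 3), 0.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    return d


def planted_distance(k, size, within=0.1, between=0.9, noise=0.0, seed=0):
    m = gs.planted_similarity(k, size, 1 - within, 1 - between, noise, seed)
    return m.to_distance(), list(m.terms)


class TestAgglomerate:
    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_unique_minimum_merged_first(self, linkage):
        dend = gs.agglomerate(three_item_matrix(), ["a", "b", "c"], linkage)
        assert sorted(dend.merges[0, :2]) == [0, 1]  # leaves a and b
        assert dend.merges[0, 2] == pytest.approx(0.1)

    @pytest.mark.parametrize("linkage", ["complete", "average"])
    def test_homogeneous_blocks_final_height(self, linkage):
        d, leaves = planted_distance(2, 3)
        dend = gs.agglomerate(d, leaves, linkage)
        assert dend.merges[-1, 2] == pytest.approx(0.9)

    def test_tied_distances_reproducible(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        leaves = list("abcd")
        d1 = gs.agglomerate(d, leaves, "average")
        d2 = gs.agglomerate(d, leaves, "average")
        assert np.array_equal(d1.merges, d2.merges)
        assert d1.cut(2).k == 2

    def test_invalid_matrices_rejected(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValidationError):
            gs.agglomerate(bad, ["a", "b"], "average")
        neg = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValidationError):
            gs.agglomerate(neg, ["a", "b"], "average")
        with pytest.raises(ValidationError):
            gs.agglomerate(three_item_matrix(), ["a", "b", "c"], "ward")


class TestCophenetic:
    def test_three_item_heights(self):
        dend = gs.agglomerate(three_item_matrix(), ["a", "b", "c"], "average")
        coph = gs.cophenetic_matrix(dend)
        assert coph[0, 1] == pytest.approx(0.1)
        assert coph[0, 2] == pytest.approx(0.9)
        assert coph[1, 2] == pytest.approx(0.9)

    @pytest.mark.parametrize("linkage", LINKAGES)
    @pytest.mark.parametrize("seed", range(5))
    def test_ultrametric_and_max_is_final_height(self, linkage, seed):
        d, leaves = planted_distance(2, 4, noise=0.3, seed=seed)
        dend = gs.agglomerate(d, leaves, linkage)
        coph = gs.cophenetic_matrix(dend)
        n = len(leaves)
        assert coph.max() == pytest.approx(dend.merges[-1, 2])
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert coph[i, k] <= max(coph[i, j], coph[j, k]) + 1e-12


class TestCCC:
    def test_perfect_on_own_cophenetic(self):
        d, leaves = planted_distance(2, 3, noise=0.2, seed=3)
        dend = gs.agglomerate(d, leaves, "average")
        assert gs.ccc(gs.cophenetic_matrix(dend), dend) == pytest.approx(1.0, abs=1e-12)

    def test_anti_ordered_distances_give_negative_correlation(self):
        y = np.full((3, 3), 0.1)
        np.fill_diagonal(y, 0.0)
        y[0, 1] = y[1, 0] = 0.9
        dend = gs.agglomerate(three_item_matrix(), ["a", "b", "c"], "average")
        score = gs.ccc(y, dend)
        oracle = np.corrcoef(squareform(y), squareform(gs.cophenetic_matrix(dend)))[0, 1]
        assert score < 0
        assert score == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_cophenet_correlation(self, seed):
        d, leaves = planted_distance(3, 3, noise=0.25, seed=seed)
        dend = gs.agglomerate(d, leaves, "complete")
        expected, _ = hierarchy.cophenet(dend.merges, squareform(d, checks=False))
        assert gs.ccc(d, dend) == pytest.approx(float(expected))

    def test_constant_distances_undefined(self):
        y = np.full((3, 3), 0.5)
        np.fill_diagonal(y, 0.0)
        dend = gs.agglomerate(three_item_matrix(), ["a", "b", "c"], "average")
        with pytest.warns(UserWarning):
            assert np.isnan(gs.ccc(y, dend))

    def test_invariant_under_leaf_permutation(self):
        d, leaves = planted_distance(2, 3, noise=0.2, seed=9)
        perm = [4, 2, 0, 5, 1, 3]
        dp = d[np.ix_(perm, perm)]
        lp = [leaves[i] for i in perm]
        s1 = gs.ccc(d, gs.agglomerate(d, leaves, "average"))
        s2 = gs.ccc(dp, gs.agglomerate(dp, lp, "average"))
        assert s1 == pytest.approx(s2)


def crossed_dendrograms():
    """Two 4-leaf trees whose nestings disagree on every counted pair."""
    leaves = ["l1", "l2", "l3", "l4"]

    def mat(pairs):
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        for (i, j), v in pairs.items():
            d[i, j] = d[j, i] = v
        return d

    d1 = gs.agglomerate(mat({(0, 1): 0.1, (2, 3): 0.2}), leaves, "average")
    d2 = gs.agglomerate(mat({(0, 2): 0.1, (1, 3): 0.2}), leaves, "average")
    return d1, d2


class TestZIndex:
    def test_identical_dendrograms_score_zero(self):
        d, leaves = planted_distance(2, 3, noise=0.1, seed=1)
        dend = gs.agglomerate(d, leaves, "average")
        assert gs.z_index(dend, dend) == 0.0

    def test_fully_crossed_nestings_score_one(self):
        d1, d2 = crossed_dendrograms()
        assert gs.z_index(d1, d2) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_range_and_symmetry(self, seed):
        d, leaves = planted_distance(2, 4, noise=0.35, seed=seed)
        a = gs.agglomerate(d, leaves, "complete")
        b = gs.agglomerate(d, leaves, "average")
        z = gs.z_index(a, b)
        assert 0.0 <= z <= 1.0
        assert z == pytest.approx(gs.z_index(b, a))

    def test_self_comparison_zero_over_many_random_trees(self):
        for seed in range(200):
            d, leaves = planted_distance(2, 4, noise=0.4, seed=seed)
            dend = gs.agglomerate(d, leaves, "average")
            assert gs.z_index(dend, dend) == 0.0

    def test_mismatched_leaves_rejected(self):
        d, leaves = planted_distance(2, 3)
        a = gs.agglomerate(d, leaves, "average")
        b = gs.agglomerate(d, [f"x{i}" for i in range(6)], "average")
        with pytest.raises(ValidationError):
            gs.z_index(a, b)


class TestSilhouette:
    def test_planted_blocks_closed_form(self):
        d, leaves = planted_distance(2, 3)
        p = Partition(assignment={t: (0 if i < 3 else 1) + 1 for i, t in enumerate(leaves)}, k=2)
        s = gs.silhouette(p, d, tuple(leaves))
        assert np.allclose(s, 0.8 / 0.9)

    def test_singleton_cluster_convention(self):
        d = three_item_matrix()
        p = Partition(assignment={"a": 1, "b": 1, "c": 2}, k=2)
        s = gs.silhouette(p, d, ("a", "b", "c"))
        assert s[2] == 0.0

    def test_equidistant_item_scores_zero(self):
        d = np.array([[0.0, 0.4, 0.4], [0.4, 0.0, 0.8], [0.4, 0.8, 0.0]])
        p = Partition(assignment={"a": 1, "b": 1, "c": 2}, k=2)
        s = gs.silhouette(p, d, ("a", "b", "c"))
        assert s[0] == 0.0  # a: mean own 0.4 equals distance to the other cluster

    def test_matches_sklearn_on_random_partition(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        d, leaves = planted_distance(3, 4, noise=0.2, seed=5)
        dend = gs.agglomerate(d, leaves, "average")
        p = dend.cut(3)
        labels = p.labels_for(dend.leaves)
        ours = gs.silhouette(p, d, dend.leaves)
        theirs = sklearn_metrics.silhouette_samples(d, labels, metric="precomputed")
        assert np.allclose(ours, theirs)


class TestOptimalK:
    def test_two_planted_blocks(self):
        d, leaves = planted_distance(2, 3)
        dend = gs.agglomerate(d, leaves, "average")
        k, score = gs.optimal_k(dend, d)
        assert k == 2
        assert score == pytest.approx(0.8 / 0.9)

    def test_three_planted_blocks(self):
        d, leaves = planted_distance(3, 3, within=0.05, between=0.95)
        dend = gs.agglomerate(d, leaves, "average")
        k, _ = gs.optimal_k(dend, d)
        assert k == 3

    def test_all_equal_distances_tie_to_smallest_k(self):
        d = np.full((5, 5), 0.5)
        np.fill_diagonal(d, 0.0)
        dend = gs.agglomerate(d, list("abcde"), "average")
        k, score = gs.optimal_k(dend, d)
        assert k == 2
        assert score == 0.0

    def test_too_small_input_rejected(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        dend = gs.agglomerate(d, ["a", "b"], "average")
        with pytest.raises(ValidationError):
            gs.optimal_k(dend, d)

    def test_asw_interpretation_bands(self):
        assert asw_label(0.1) == "artificial"
        assert asw_label(0.4) == "intermediate"
        assert asw_label(0.7) == "structured"


@st.composite
def distance_matrices(draw, max_n=6):
    n = draw(st.integers(min_value=3, max_value=max_n))
    tri = draw(
        st.lists(
            st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
            min_size=n * (n - 1) // 2, max_size=n * (n - 1) // 2,
        )
    )
    d = np.zeros((n, n))
    d[np.triu_indices(n, k=1)] = tri
    return d + d.T


@settings(derandomize=True, max_examples=40, deadline=None)
@given(distance_matrices(), st.sampled_from(LINKAGES))
def test_cophenetic_is_ultrametric_on_arbitrary_inputs(d, linkage):
    n = d.shape[0]
    dend = gs.agglomerate(d, [f"t{i}" for i in range(n)], linkage)
    coph = gs.cophenetic_matrix(dend)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert coph[i, k] <= max(coph[i, j], coph[j, k]) + 1e-12


@settings(derandomize=True, max_examples=40, deadline=None)
@given(distance_matrices())
def test_ccc_bounded_and_zindex_vanishes_on_self(d):
    n = d.shape[0]
    dend = gs.agglomerate(d, [f"t{i}" for i in range(n)], "average")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant matrices make CCC undefined
        score = gs.ccc(d, dend)
    assert np.isnan(score) or -1.0 <= score <= 1.0 + 1e-12
    assert gs.z_index(dend, dend) == 0.0


class TestNewick:
    def test_parses_with_dendropy_and_keeps_leaves(self):
        dendropy = pytest.importorskip("dendropy")
        d, leaves = planted_distance(2, 3, noise=0.1, seed=2)
        dend = gs.agglomerate(d, leaves, "average")
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(leaves)
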