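"""Objective functions: discriminant ratio, correlation, PCA, clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glomnet.metrics import (DegenerateDataError, concentration_correlation,
                             fisher_discriminant_ratio, hierarchical_kmeans,
                             pca_scores, pearson_correlation)


class TestFDR:
    def test_two_separated_1d_classes(self):
        X = np.array([0.0, 1.0, 3.0, 4.0])
        labels = ["a", "a", "b", "b"]
        assert fisher_discriminant_ratio(X, labels) == pytest.approx(9.0)

    def test_identical_class_means_give_zero(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        assert fisher_discriminant_ratio(X, ["a", "a", "b", "b"]) == 0.0

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(24, 5))
        labels = np.repeat(list("abcd"), 6)
        f0 = fisher_discriminant_ratio(X, labels)
        f1 = fisher_discriminant_ratio(X + 17.3, labels)
        assert f1 == pytest.approx(f0, rel=1e-10)

    def test_degenerate_within_scatter_flagged(self):
        X = np.array([[1.0], [1.0], [5.0], [5.0]])
        with pytest.raises(DegenerateDataError):
            fisher_discriminant_ratio(X, ["a", "a", "b", "b"])

    def test_requires_two_classes_and_two_samples_each(self):
        with pytest.raises(ValueError):
            fisher_discriminant_ratio(np.ones((4, 2)), ["a"] * 4)
        with pytest.raises(ValueError):
            fisher_discriminant_ratio(np.arange(3.0), ["a", "a", "b"])

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(1e-3, 1e3),
           seed=st.integers(0, 2**16))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        f0 = fisher_discriminant_ratio(X, labels)
        f1 = fisher_discriminant_ratio(X * scale, labels)
        assert f1 == pytest.approx(f0, rel=1e-8)


class TestPCC:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_case(self):
        # cov = 4.5, var_x = 5, var_y = 4.75 -> r = 4.5 / sqrt(23.75)
        r = pearson_correlation([1, 2, 3, 4], [1, 2, 2, 4])
        assert r == pytest.approx(0.9234, abs=1e-3)

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateDataError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(float, (8, 2),
                      elements=st.floats(-100, 100, allow_nan=False)))
    def test_bounds(self, xy):
        x, y = xy[:, 0], xy[:, 1]
        try:
            r = pearson_correlation(x, y)
        except DegenerateDataError:
            return
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


class TestConcentrationCorrelation:
    def _linear_inputs(self, rng):
        S = rng.uniform(0, 20, size=(3, 8))   # low enough never to clip
        conc = np.array([0.4, 0.6, 0.8, 1.0, 1.2, 1.4])
        X = np.vstack([S[i] * c for i in range(3) for c in conc])
        odors = np.repeat(["A", "B", "C"], 6)
        return X, odors, np.tile(conc, 3)

    def test_mean_scalarization_on_linear_inputs_is_one(self, rng):
        X, odors, conc = self._linear_inputs(rng)
        cc = concentration_correlation(X, odors, conc, method="mean")
        assert cc.mean == pytest.approx(1.0)
        assert cc.sd == pytest.approx(0.0, abs=1e-12)

    def test_pooled_on_linear_inputs_below_one(self, rng):
        X, odors, conc = self._linear_inputs(rng)
        cc = concentration_correlation(X, odors, conc, method="pooled")
        assert 0.0 < cc.mean < 1.0

    def test_concentration_independent_responses_excluded(self):
        # identical response vectors at every concentration: the scalarized
        # response is constant, so the per-odor PCC is undefined
        X = np.tile(np.arange(4.0), (6, 1))
        odors = np.repeat(["A"], 6)
        conc = np.tile([0.5, 1.0, 1.5], 2)
        with pytest.raises(DegenerateDataError):
            concentration_correlation(X, odors, conc, method="mean")
        # under pooling only a fully flat response is degenerate
        with pytest.raises(DegenerateDataError):
            concentration_correlation(np.ones((6, 4)), odors, conc,
                                      method="pooled")
        # ...while per-glomerulus structure keeps it defined (near zero)
        cc = concentration_correlation(X, odors, conc, method="pooled")
        assert cc.per_odor["A"] == pytest.approx(0.0, abs=1e-12)

    def test_negating_scalarization_negates_pcc(self, rng):
        X, odors, conc = self._linear_inputs(rng)
        cc_pos = concentration_correlation(X, odors, conc, method="mean")
        cc_neg = concentration_correlation(-X, odors, conc, method="mean")
        assert cc_neg.mean == pytest.approx(-cc_pos.mean)

    def test_requires_multiple_concentrations(self):
        X = np.ones((2, 3))
        with pytest.raises(ValueError):
            concentration_correlation(X, ["A", "A"], [1.0, 1.0])


class TestPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=4)
        X = np.outer(u, v)
        _, evr = pca_scores(X, 2)
        assert evr[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(20, 6))
        _, evr = pca_scores(X)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(15, 5))
        scores, _ = pca_scores(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = U * s
        for j in range(scores.shape[1]):
            match = (np.allclose(scores[:, j], oracle[:, j], atol=1e-8)
                     or np.allclose(scores[:, j], -oracle[:, j], atol=1e-8))
            assert match, f"component {j} disagrees with SVD"

    def test_score_columns_orthogonal(self, rng):
        X = rng.normal(size=(30, 8))
        scores, _ = pca_scores(X)
        G = scores.T @ scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


def brute_force_best_bisection(X):
    """Exhaustive minimum-total-WSS 2-partition (oracle for small n)."""
    n = X.shape[0]
    best, best_parts = np.inf, None
    for mask in range(1, 2 ** (n - 1)):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        if sel.sum() in (0, n):
            continue
        wss = sum(((X[g] - X[g].mean(axis=0)) ** 2).sum()
                  for g in (sel, ~sel))
        if wss < best:
            best, best_parts = wss, frozenset(
                [frozenset(np.where(sel)[0]), frozenset(np.where(~sel)[0])])
    return best_parts


class TestHierarchicalKMeans:
    def test_leaf_count(self, rng):
        X = rng.normal(size=(9, 3))
        root = hierarchical_kmeans(X, seed=0)
        assert len(root.leaves()) == 9
        assert sorted(lf.members[0] for lf in root.leaves()) == list(range(9))

    def test_duplicated_points_merge_at_height_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        root = hierarchical_kmeans(X, seed=0)
        dup = root.cut(2)
        assert [2] in dup
        def heights(node):
            yield node.height
            for ch in node.children:
                yield from heights(ch)
        pair = [c for c in dup if len(c) == 2][0]
        sub = [nd for nd in _walk(root) if sorted(nd.members) == pair][0]
        assert sub.height == pytest.approx(0.0)

    def test_top_split_recovers_separated_blobs(self, rng):
        centers = np.array([[0.0] * 4, [60.0] * 4])
        X = np.vstack([c + rng.normal(scale=1.0, size=(6, 4))
                       for c in centers])
        root = hierarchical_kmeans(X, seed=0)
        got = frozenset(frozenset(c) for c in root.cut(2))
        assert got == brute_force_best_bisection(X)

    def test_determinism(self, rng):
        X = rng.normal(size=(12, 4))
        n1 = hierarchical_kmeans(X, seed=5).to_newick()
        n2 = hierarchical_kmeans(X, seed=5).to_newick()
        assert n1 == n2

    def test_newick_is_parseable(self, rng):
        import dendropy
        X = rng.normal(size=(7, 3))
        labels = [f"s{i}" for i in range(7)]
        nwk = hierarchical_kmeans(X, labels, seed=0).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 7


def _walk(node):
    yield node
    for ch in node.children:
        yield from _walk(ch)
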