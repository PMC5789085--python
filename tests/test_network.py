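import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mhonet.network import (
    CoexpressionNetwork,
    ScaleFreeFitError,
    cluster_modules,
    merge_modules,
    pick_soft_threshold,
    scale_free_fit,
    similarity_matrix,
    soft_adjacency,
    topological_overlap,
)


def random_similarity(seed, n=12):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 8))
    return similarity_matrix(x)


def brute_force_tom(a):
    """Definitional double-loop TOM evaluation."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestSimilarity:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(10)
        x = np.vstack([g, -g, rng.standard_normal(10)])
        s = similarity_matrix(x)
        assert s[0, 0] == pytest.approx(1.0)
        assert s[0, 1] == pytest.approx(-1.0)

    def test_four_gene_toy_matches_corrcoef(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 9))
        np.testing.assert_allclose(similarity_matrix(x), np.corrcoef(x), atol=1e-12)

    def test_zero_variance_gene_is_error(self):
        x = np.vstack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            similarity_matrix(x)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.ones((4, 2)))


class TestSoftAdjacency:
    def test_known_values(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = soft_adjacency(s, 6)
        assert a[0, 1] == pytest.approx(0.5**6)
        assert soft_adjacency(np.array([[1.0, -0.5], [-0.5, 1.0]]), 6)[0, 1] == pytest.approx(0.5**6)
        assert a[0, 0] == 1.0

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            soft_adjacency(np.eye(2), 0.5)

    @given(st.integers(0, 1000))
    def test_symmetric_unit_interval(self, seed):
        s = random_similarity(seed)
        a = soft_adjacency(s, 6)
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    @given(st.integers(0, 1000))
    def test_monotone_decreasing_in_beta(self, seed):
        s = random_similarity(seed)
        a2, a5 = soft_adjacency(s, 2), soft_adjacency(s, 5)
        off = ~np.eye(s.shape[0], dtype=bool)
        assert np.all(a5[off] <= a2[off] + 1e-15)
        # invariant where |s| is exactly 0 or 1
        s01 = np.eye(3)
        np.testing.assert_array_equal(soft_adjacency(s01, 2), soft_adjacency(s01, 9))


class TestScaleFree:
    def test_exact_power_law_fits_well(self):
        # construct connectivities following k^-2 frequencies
        rng = np.random.default_rng(0)
        k = (rng.pareto(2.0, 4000) + 1) * 3
        from mhonet.network import scale_free_fit_from_connectivity

        assert scale_free_fit_from_connectivity(k) > 0.85

    def test_constant_degree_returns_zero(self):
        a = np.ones((5, 5))
        with pytest.warns(UserWarning):
            assert scale_free_fit(a) == 0.0

    def test_increasing_frequency_slope_rejected(self):
        from mhonet.network import scale_free_fit_from_connectivity

        # heavier mass at high degree -> positive slope -> fit forced to 0
        k = np.concatenate([np.full(10, 1.0), np.full(100, 10.0)])
        assert scale_free_fit_from_connectivity(k, n_bins=2) == 0.0

    def test_toy_adjacency_against_direct_regression(self):
        a = soft_adjacency(random_similarity(3, n=40), 4)
        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        mk, fr = [], []
        for b in range(10):
            if np.any(which == b):
                mk.append(k[which == b].mean())
                fr.append((which == b).mean())
        slope, intercept = np.polyfit(np.log10(mk), np.log10(fr), 1)
        if slope >= 0:
            expected = 0.0
        else:
            resid = np.log10(fr) - (slope * np.log10(mk) + intercept)
            expected = 1 - np.sum(resid**2) / np.sum((np.log10(fr) - np.mean(np.log10(fr))) ** 2)
            expected = max(0.0, expected)
        assert scale_free_fit(a) == pytest.approx(expected, abs=1e-12)


class TestPickSoftThreshold:
    def test_returns_smallest_qualifying_power(self, small_logcpm):
        lcpm, _, _, _ = small_logcpm
        s = similarity_matrix(lcpm)
        beta, curve = pick_soft_threshold(s)
        assert curve.loc[beta, "fit"] >= 0.8
        below = curve.loc[: beta - 1, "fit"] if beta > 1 else []
        assert all(f < 0.8 for f in below)

    def test_degenerate_similarity_raises_with_curve(self):
        s = np.full((30, 30), 0.5)
        np.fill_diagonal(s, 1.0)
        with pytest.raises(ScaleFreeFitError) as exc:
            with pytest.warns(UserWarning):
                pick_soft_threshold(s)
        assert "fit" in exc.value.fit_curve.columns

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(np.eye(3), candidate_powers=[])


class TestTOM:
    def test_two_connected_nodes(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_no_shared_neighbors(self):
        a = np.eye(4)
        tom = topological_overlap(a)
        assert tom[0, 1] == 0.0

    def test_three_node_hand_value(self):
        # a_12 = a_13 = a_23 = 0.5: TOM_12 = (0.25 + 0.5)/(1 + 1 - 0.5) = 0.5
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        assert topological_overlap(a)[0, 1] == pytest.approx(0.5)

    @given(st.integers(0, 500), st.integers(3, 20))
    def test_matches_brute_force_double_loop(self, seed, n):
        a = soft_adjacency(random_similarity(seed, n=n), 3)
        np.testing.assert_allclose(
            topological_overlap(a), brute_force_tom(a), atol=1e-10
        )

    @given(st.integers(0, 500))
    def test_symmetric_unit_interval(self, seed):
        tom = topological_overlap(soft_adjacency(random_similarity(seed), 6))
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(ValueError):
            topological_overlap(a)


@pytest.fixture(scope="module")
def fitted_network(small_logcpm):
    lcpm, _, _, _ = small_logcpm
    return CoexpressionNetwork().fit(lcpm.to_numpy().T), lcpm


class TestModules:
    def test_planted_modules_recovered(self, fitted_network, small_logcpm):
        net, _ = fitted_network
        _, _, _, truth_labels = small_logcpm
        from sklearn.metrics import rand_score

        for m in (1, 2, 3):
            mask = truth_labels == m
            detected = net.labels_[mask]
            vals, counts = np.unique(detected[detected > 0], return_counts=True)
            recall = counts.max() / mask.sum() if counts.size else 0.0
            assert recall >= 0.8, f"planted module {m} recall {recall}"
        planted = truth_labels > 0
        assert rand_score(truth_labels[planted], net.labels_[planted]) >= 0.8

    def test_min_size_rule_unassigns_small_branches(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(60)
        x = np.vstack(
            [f + 0.05 * rng.standard_normal(60) for _ in range(9)]
            + [rng.standard_normal(60) for _ in range(30)]
        )
        tom = topological_overlap(soft_adjacency(similarity_matrix(x), 6))
        part = cluster_modules(tom, min_module_size=10)
        assert np.all(part.labels[:9] == 0)  # 9-gene branch below minimum
        part2 = cluster_modules(tom, min_module_size=9)
        assert len(set(part2.labels[:9])) == 1 and part2.labels[0] > 0

    def test_duplicate_genes_cluster_together(self):
        rng = np.random.default_rng(3)
        g = rng.standard_normal(15)
        x = np.vstack([g, g + 1.0, rng.standard_normal((12, 15))])
        tom = topological_overlap(soft_adjacency(similarity_matrix(x), 6))
        z = cluster_modules(tom, min_module_size=2).linkage
        # duplicated genes are each other's closest neighbours; note that the
        # TOM of two identical genes is below 1 (shared-neighbour term uses
        # squared adjacencies), so the merge height is small but not zero
        first = z[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(1.0 - tom[0, 1])
        assert first[2] < 0.5

    def test_labels_contiguous_sorted_by_size(self, fitted_network):
        net, _ = fitted_network
        labels = net.labels_
        present = sorted(set(labels[labels > 0]))
        assert present == list(range(1, len(present) + 1))
        sizes = [np.sum(labels == m) for m in present]
        assert sizes == sorted(sizes, reverse=True)


class TestMerge:
    def _modules_from_factor(self, r, seed=0):
        rng = np.random.default_rng(seed)
        n = 30
        f1 = rng.standard_normal(n)
        f2 = r * f1 + np.sqrt(1 - r**2) * rng.standard_normal(n)
        x = np.vstack(
            [f1 + 0.3 * rng.standard_normal(n) for _ in range(12)]
            + [f2 + 0.3 * rng.standard_normal(n) for _ in range(12)]
        )
        labels = np.array([1] * 12 + [2] * 12)
        from mhonet.network import ModulePartition

        return x, ModulePartition(labels=labels)

    def test_same_factor_copies_merged(self):
        x, part = self._modules_from_factor(r=0.999)
        merged = merge_modules(x, part, merge_cor=0.75)
        assert merged.n_modules == 1
        assert merged.merge_history

    def test_orthogonal_factors_unmerged(self):
        x, part = self._modules_from_factor(r=0.0)
        merged = merge_modules(x, part, merge_cor=0.75)
        assert merged.n_modules == 2

    @pytest.mark.parametrize("r, expect_merged", [(0.9, True), (0.3, False)])
    def test_factor_correlation_thresholding(self, r, expect_merged):
        x, part = self._modules_from_factor(r=r, seed=4)
        merged = merge_modules(x, part, merge_cor=0.75)
        assert (merged.n_modules == 1) == expect_merged


class TestEstimator:
    def test_fitted_attributes(self, fitted_network, small_logcpm):
        net, lcpm = fitted_network
        assert net.labels_.shape == (lcpm.shape[0],)
        assert net.beta_ >= 1
        assert net.tom_.shape == (lcpm.shape[0],) * 2
        assert 0 <= net.scale_free_fit_ <= 1

    def test_get_params_roundtrip(self):
        net = CoexpressionNetwork(min_module_size=5, cut_height=0.9)
        params = net.get_params()
        assert params["min_module_size"] == 5
        from sklearn.base import clone

        assert clone(net).get_params() == params
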