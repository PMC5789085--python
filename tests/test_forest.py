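import itertools

import numpy as np
import pandas as pd
import pytest

from mhonet.forest import (
    BalancedRandomForestClassifier,
    OOBForestRegressor,
    oob_performance,
    permutation_vim,
    rank_metabolic_drivers,
    select_variables,
)

Y_8V21 = np.array([1] * 8 + [0] * 21)


def pairwise_auc(scores, truth):
    """Exhaustive pairwise-comparison (Mann-Whitney) AUC, ties count half."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def separating_forest():
    rng = np.random.default_rng(0)
    X = np.column_stack([Y_8V21 + 0.01 * rng.standard_normal(29),
                         rng.standard_normal(29)])
    return BalancedRandomForestClassifier(ntree=500, random_state=0).fit(X, Y_8V21), X


class TestForestFit:
    def test_separating_feature_perfect_oob(self, separating_forest):
        forest, _ = separating_forest
        perf = oob_performance(forest)
        assert perf["oob_error"] <= 0.05
        assert perf["auc"] >= 0.98
        assert perf["sensitivity"] >= 0.95 and perf["specificity"] >= 0.95

    def test_null_features_auc_near_half(self):
        aucs = []
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            X = rng.standard_normal((29, 10))
            f = BalancedRandomForestClassifier(ntree=200, random_state=s).fit(X, Y_8V21)
            aucs.append(oob_performance(f)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((29, 5))
        f1 = BalancedRandomForestClassifier(ntree=150, random_state=9).fit(X, Y_8V21)
        f2 = BalancedRandomForestClassifier(ntree=150, random_state=9).fit(X, Y_8V21)
        np.testing.assert_array_equal(f1.oob_decision_function_, f2.oob_decision_function_)
        v1 = permutation_vim(f1, X, n_perm=300, seed=4)
        v2 = permutation_vim(f2, X, n_perm=300, seed=4)
        np.testing.assert_array_equal(v1, v2)

    def test_balanced_bootstrap_composition(self, separating_forest):
        forest, _ = separating_forest
        n_minority = 8
        for boot in forest.bootstrap_indices_[:50]:
            drawn = Y_8V21[boot]
            assert len(boot) == 2 * n_minority
            assert (drawn == 1).sum() == n_minority
            assert (drawn == 0).sum() == n_minority

    def test_unbalanced_bootstrap_size_n(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((29, 3))
        f = BalancedRandomForestClassifier(
            ntree=20, balanced=False, random_state=0
        ).fit(X, Y_8V21)
        assert all(len(b) == 29 for b in f.bootstrap_indices_)

    def test_predict_api(self, separating_forest):
        forest, X = separating_forest
        proba = forest.predict_proba(X)
        assert proba.shape == (29, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (forest.predict(X) == Y_8V21).mean() > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            BalancedRandomForestClassifier(ntree=5).fit(np.ones((4, 2)), [1, 1, 1, 1])

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            BalancedRandomForestClassifier(ntree=5).fit(np.empty((4, 0)), [0, 1, 0, 1])

    def test_mtry_default_is_half_p(self, separating_forest):
        forest, _ = separating_forest
        assert forest.mtry_ == 1  # floor(2/2)
        rng = np.random.default_rng(3)
        f = BalancedRandomForestClassifier(ntree=5, random_state=0).fit(
            rng.standard_normal((29, 9)), Y_8V21
        )
        assert f.mtry_ == 4


class TestOOBPerformance:
    def test_auc_matches_exhaustive_pairwise_oracle(self):
        for s in range(6):
            rng = np.random.default_rng(s)
            n = rng.integers(6, 13)
            y = np.array([1] * (n // 2) + [0] * (n - n // 2))
            X = rng.standard_normal((n, 4))
            forest = BalancedRandomForestClassifier(ntree=400, random_state=s).fit(X, y)
            perf = oob_performance(forest)
            votes = forest.oob_decision_function_[:, 1]
            assert perf["auc"] == pytest.approx(pairwise_auc(votes, y), abs=1e-10)

    def test_votes_equal_labels_are_perfect(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([Y_8V21.astype(float)])
        f = BalancedRandomForestClassifier(ntree=300, random_state=0).fit(X, Y_8V21)
        perf = oob_performance(f)
        assert perf["auc"] == 1.0
        cm = perf["confusion"]
        assert cm["tp"] == 8 and cm["tn"] == 21

    def test_sample_never_oob_is_error(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((29, 3))
        f = BalancedRandomForestClassifier(ntree=1, random_state=0).fit(X, Y_8V21)
        with pytest.raises(ValueError, match="ntree"):
            oob_performance(f)


class TestVIM:
    def test_vectorized_vim_matches_naive_bookkeeping(self):
        """Oracle: per-tree, per-feature loop re-implementing the definition."""
        rng = np.random.default_rng(0)
        X = np.column_stack([Y_8V21 + 0.3 * rng.standard_normal(29),
                             rng.standard_normal(29),
                             rng.standard_normal(29)])
        forest = BalancedRandomForestClassifier(ntree=3, random_state=7).fit(X, Y_8V21)
        n_perm = 3  # ceil(3/3) = 1 draw per tree
        got = permutation_vim(forest, X, n_perm=n_perm, seed=5)

        rng_oracle = np.random.default_rng(5)
        varying = np.flatnonzero(np.ptp(X, axis=0) > 0)
        total = np.zeros(X.shape[1])
        used = 0
        for t, tree in enumerate(forest.estimators_):
            oob = forest.oob_indices_[t]
            if oob.size == 0:
                continue
            used += 1
            x_oob = X[oob]
            t_oob = forest._y_encoded_[oob]
            base = forest.oob_tree_errors_[t]
            # mirror the implementation's draw order: features x draws
            perms = {k: rng_oracle.permutation(oob.size) for k in varying}
            for k in varying:
                xp = x_oob.copy()
                xp[:, k] = x_oob[perms[k], k]
                err2 = np.mean(tree.predict(xp) != t_oob)
                total[k] += err2 - base
        np.testing.assert_allclose(got, total / used, atol=1e-12)

    def test_pure_noise_features_have_null_vim(self):
        # fresh noise matrix per replicate: within one finite dataset a noise
        # feature can be chance-correlated with the labels, which is a real
        # (not Monte-Carlo) effect; the null distribution is over datasets
        vals = []
        for r in range(5):
            rng = np.random.default_rng(100 + r)
            X = rng.standard_normal((29, 15))
            f = BalancedRandomForestClassifier(ntree=300, random_state=r).fit(X, Y_8V21)
            vals.append(permutation_vim(f, X, n_perm=300, seed=r))
        vals = np.concatenate(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * se + 1e-3
        assert np.mean(np.abs(vals - vals.mean()) <= 2 * vals.std(ddof=1)) >= 0.9

    def test_separating_feature_has_maximal_vim(self, separating_forest):
        forest, X = separating_forest
        vim = permutation_vim(forest, X, n_perm=500, seed=0)
        assert np.argmax(vim) == 0
        assert vim[0] > 0.05

    def test_constant_feature_gets_zero(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(29), rng.standard_normal(29)])
        f = BalancedRandomForestClassifier(ntree=50, random_state=0).fit(X, Y_8V21)
        vim = permutation_vim(f, X, n_perm=50, seed=0)
        assert vim[0] == 0.0


class TestSelection:
    def test_informative_features_recovered(self):
        n1, n0 = 30, 50
        y = np.array([1] * n1 + [0] * n0)
        rng = np.random.default_rng(0)
        X = np.column_stack(
            [1.5 * y + rng.standard_normal(n1 + n0) for _ in range(5)]
            + [rng.standard_normal(n1 + n0) for _ in range(30)]
        )
        sel = select_variables(X, y, ntree=200, n_replicates=6, n_eval=4, seed=0)
        informative = {f"f{i}" for i in range(5)}
        pred = set(sel.prediction_set)
        assert len(informative & pred) >= 4
        assert len(pred - informative) <= 2
        # nesting invariants
        assert pred <= set(sel.interpretation_set)
        assert all(sel.mean_vim[f] > 0 for f in sel.interpretation_set)

    def test_single_informative_feature_selected_alone(self):
        y = Y_8V21
        rng = np.random.default_rng(3)
        X = np.column_stack([3.0 * y + 0.3 * rng.standard_normal(29),
                             rng.standard_normal(29), rng.standard_normal(29),
                             rng.standard_normal(29)])
        sel = select_variables(X, y, ntree=300, n_replicates=6, n_eval=4, seed=1)
        assert sel.prediction_set[:1] == ["f0"]
        assert len(sel.prediction_set) <= 2

    def test_all_noise_gives_sparse_or_empty_selection(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 20))
        y = np.array([1] * 25 + [0] * 35)
        sel = select_variables(X, y, ntree=200, n_replicates=6, n_eval=3, seed=2)
        assert len(sel.prediction_set) <= 3


class TestDrivers:
    def _clinical(self, rng, n):
        return pd.DataFrame(
            {
                "hscrp": rng.standard_normal(n),
                "tg_hdl": rng.standard_normal(n),
                "glucose": rng.standard_normal(n),
                "homa_ir": rng.standard_normal(n),
            }
        )

    def test_tg_hdl_driven_expression_top_ranked(self):
        rng = np.random.default_rng(0)
        clin = self._clinical(rng, 29)
        expr = np.vstack(
            [2.0 * clin["tg_hdl"].to_numpy() + 0.4 * rng.standard_normal(29)
             for _ in range(15)]
        )
        res = rank_metabolic_drivers(expr, clin, Y_8V21, ntree=300, seed=0)
        assert res.top_counts["tg_hdl"] >= 0.9 * 15
        assert set(res.single_parameter_auc) == {"hscrp", "tg_hdl", "glucose", "homa_ir"}

    def test_independent_expression_spreads_top_counts(self):
        rng = np.random.default_rng(1)
        clin = self._clinical(rng, 29)
        expr = rng.standard_normal((24, 29))
        res = rank_metabolic_drivers(expr, clin, Y_8V21, ntree=200, seed=0)
        assert res.top_counts.max() <= 0.6 * 24  # roughly uniform

    def test_duplicate_parameter_excluded_ranking_unchanged(self):
        rng = np.random.default_rng(2)
        clin = self._clinical(rng, 29)
        expr = np.vstack([2.0 * clin["tg_hdl"].to_numpy() + 0.4 * rng.standard_normal(29)
                          for _ in range(6)])
        base = rank_metabolic_drivers(expr, clin, Y_8V21, ntree=200, seed=0)
        clin_dup = clin.copy()
        clin_dup["tg_hdl_copy"] = clin["tg_hdl"]
        with pytest.warns(UserWarning, match="duplicates"):
            dup = rank_metabolic_drivers(
                expr, clin_dup, Y_8V21,
                parameters=("hscrp", "tg_hdl", "glucose", "homa_ir", "tg_hdl_copy"),
                ntree=200, seed=0,
            )
        assert dup.excluded == ["tg_hdl_copy"]
        pd.testing.assert_series_equal(base.top_parameter, dup.top_parameter)

    def test_constant_parameter_excluded(self):
        rng = np.random.default_rng(3)
        clin = self._clinical(rng, 29)
        clin["glucose"] = 90.0
        expr = rng.standard_normal((3, 29))
        with pytest.warns(UserWarning, match="constant"):
            res = rank_metabolic_drivers(expr, clin, Y_8V21, ntree=100, seed=0)
        assert "glucose" in res.excluded


class TestRegressor:
    def test_oob_prediction_tracks_signal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = 2.0 * X[:, 1] + 0.3 * rng.standard_normal(60)
        reg = OOBForestRegressor(ntree=300, random_state=0).fit(X, y)
        assert np.corrcoef(reg.oob_prediction_, y)[0, 1] > 0.8
        vim = permutation_vim(reg, X, n_perm=300, seed=0)
        assert np.argmax(vim) == 1
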