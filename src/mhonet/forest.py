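"""Balanced random forests with OOB evaluation and permutation importance.

Class imbalance (8 MHO vs 21 MAO) is handled by a balanced bootstrap:
each tree is grown on an equal number of samples drawn with replacement
from every class (the minority-class count per class), so the per-tree
prediction error is not dominated by the majority class.  Following the
study design, ``mtry`` defaults to floor(p/2) candidate features per
split — deliberately not the conventional sqrt(p) — and forests are
large (``ntree`` = 10,000) for stable out-of-bag (OOB) estimates.

The permutation variable importance VIM_k of feature k is the mean over
trees of errOOB2^k - errOOB1: the increase of a tree's OOB error when
feature k is permuted within its OOB set.  ``nPerm`` total permutation
draws are spread across the trees.  Variable selection ranks features
by replicate-averaged VIM, derives a noise threshold from the
negative-VIM features, and walks a nested forward pass keeping the
smallest prefix whose OOB AUC is within one standard error of the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BalancedRandomForestClassifier",
    "OOBForestRegressor",
    "oob_performance",
    "permutation_vim",
    "select_variables",
    "rank_metabolic_drivers",
    "VariableSelectionResult",
    "DriverRanking",
]


def _default_mtry(p: int, mtry) -> int:
    m = max(1, p // 2) if mtry is None else int(mtry)
    if not 1 <= m <= p:
        raise ValueError(f"mtry must be in [1, {p}], got {m}")
    return m


class _ForestBase(BaseEstimator):
    def __init__(self, ntree: int = 10000, mtry: int | None = None, random_state: int = 0):
        self.ntree = ntree
        self.mtry = mtry
        self.random_state = random_state

    def _tree_seeds(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        return rng.integers(0, 2**31 - 1, size=n)


class BalancedRandomForestClassifier(ClassifierMixin, _ForestBase):
    """Random-forest classifier with balanced per-tree bootstraps.

    Each tree draws, with replacement, the minority-class count of
    samples from *every* class (``balanced=True``; a plain bootstrap of
    size n otherwise), splits on Gini impurity considering ``mtry``
    (default floor(p/2)) candidate features per split, and accumulates
    OOB votes from the trees for which a sample was out of bag.
    Deterministic under a fixed ``random_state``.
    """

    def __init__(self, ntree: int = 10000, mtry: int | None = None,
                 balanced: bool = True, random_state: int = 0):
        super().__init__(ntree=ntree, mtry=mtry, random_state=random_state)
        self.balanced = balanced

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-d with at least one feature")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        n, p = X.shape
        mtry = _default_mtry(p, self.mtry)
        class_idx = [np.flatnonzero(y_enc == c) for c in range(len(self.classes_))]
        n_draw = min(len(ix) for ix in class_idx)

        seeds = self._tree_seeds(self.ntree)
        estimators, oob_indices, boot_indices, tree_errors = [], [], [], []
        votes = np.zeros((n, len(self.classes_)))
        oob_counts = np.zeros(n)
        for t in range(self.ntree):
            rng = np.random.default_rng(seeds[t])
            if self.balanced:
                boot = np.concatenate([rng.choice(ix, size=n_draw, replace=True)
                                       for ix in class_idx])
            else:
                boot = rng.choice(n, size=n, replace=True)
            oob = np.setdiff1d(np.arange(n), boot)
            boot_indices.append(boot)
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=mtry,
                random_state=int(seeds[t] % (2**31 - 1)),
            ).fit(X[boot], y_enc[boot])
            estimators.append(tree)
            oob_indices.append(oob)
            if oob.size:
                pred = tree.predict(X[oob])
                tree_errors.append(float(np.mean(pred != y_enc[oob])))
                votes[oob, pred] += 1.0
                oob_counts[oob] += 1.0
            else:
                tree_errors.append(np.nan)

        self.n_features_in_ = p
        self.mtry_ = mtry
        self.estimators_ = estimators
        self.oob_indices_ = oob_indices
        self.bootstrap_indices_ = boot_indices
        self.oob_tree_errors_ = np.asarray(tree_errors)
        self.oob_counts_ = oob_counts
        with np.errstate(invalid="ignore"):
            self.oob_decision_function_ = votes / np.maximum(oob_counts, 1)[:, None]
        self._y_encoded_ = y_enc
        self.y_ = y
        pos_frac = self.oob_decision_function_[:, 1]
        pred = (pos_frac > 0.5).astype(int)
        seen = oob_counts > 0
        self.oob_error_ = float(np.mean(pred[seen] != y_enc[seen])) if seen.any() else np.nan
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            votes[np.arange(X.shape[0]), tree.predict(X)] += 1.0
        return votes / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class OOBForestRegressor(RegressorMixin, _ForestBase):
    """Bootstrap forest regressor (variance-reduction splits) with OOB MSE."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        mtry = _default_mtry(p, self.mtry)
        seeds = self._tree_seeds(self.ntree)
        estimators, oob_indices, tree_errors = [], [], []
        pred_sum = np.zeros(n)
        oob_counts = np.zeros(n)
        for t in range(self.ntree):
            rng = np.random.default_rng(seeds[t])
            boot = rng.choice(n, size=n, replace=True)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                criterion="squared_error", max_features=mtry,
                random_state=int(seeds[t] % (2**31 - 1)),
            ).fit(X[boot], y[boot])
            estimators.append(tree)
            oob_indices.append(oob)
            if oob.size:
                pred = tree.predict(X[oob])
                tree_errors.append(float(np.mean((pred - y[oob]) ** 2)))
                pred_sum[oob] += pred
                oob_counts[oob] += 1.0
            else:
                tree_errors.append(np.nan)
        self.n_features_in_ = p
        self.mtry_ = mtry
        self.estimators_ = estimators
        self.oob_indices_ = oob_indices
        self.oob_tree_errors_ = np.asarray(tree_errors)
        self.oob_counts_ = oob_counts
        self.y_ = y
        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = pred_sum / np.maximum(oob_counts, 1)
        seen = oob_counts > 0
        self.oob_error_ = float(np.mean((self.oob_prediction_[seen] - y[seen]) ** 2))
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.estimators_], axis=0)


def oob_performance(forest: BalancedRandomForestClassifier, pos_label=None) -> dict:
    """OOB AUC, sensitivity, specificity, error and confusion matrix.

    The AUC is the rank statistic of OOB positive-class vote fractions
    (ties count one half); sensitivity/specificity threshold the vote
    fraction at 0.5 (ties go to the reference class).  The positive
    class defaults to ``classes_[1]`` — encode MAO=0, MHO=1.
    """
    check_is_fitted(forest, "estimators_")
    if np.any(forest.oob_counts_ == 0):
        raise ValueError(
            "some samples were never out of bag; increase ntree for stable OOB estimates"
        )
    classes = forest.classes_
    if pos_label is None:
        pos_label = classes[1]
    pos_col = int(np.flatnonzero(classes == pos_label)[0])
    votes = forest.oob_decision_function_[:, pos_col]
    truth = (forest.y_ == pos_label).astype(int)
    pred = (votes > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return {
        "auc": float(roc_auc_score(truth, votes)),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "oob_error": float(np.mean(pred != truth)),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def permutation_vim(
    forest,
    X,
    y=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation variable importance VIM_k per feature.

    For each tree, the feature is permuted within the tree's OOB set
    (``ceil(n_perm / ntree)`` draws, averaged) and the OOB error
    (misclassification rate, or MSE for regression forests) recomputed;
    VIM_k is the mean over trees of the error increase.  Constant
    features get VIM 0 by definition.
    """
    check_is_fitted(forest, "estimators_")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    is_classifier = isinstance(forest, BalancedRandomForestClassifier)
    target = forest._y_encoded_ if is_classifier else forest.y_
    ntree = len(forest.estimators_)
    draws = max(1, int(np.ceil(n_perm / ntree)))
    varying = np.flatnonzero(np.ptp(X, axis=0) > 0)
    rng = np.random.default_rng(seed)
    vim_sum = np.zeros(p)
    used = 0
    for t, tree in enumerate(forest.estimators_):
        oob = forest.oob_indices_[t]
        if oob.size == 0:
            continue
        used += 1
        x_oob = X[oob]
        t_oob = target[oob]
        base = forest.oob_tree_errors_[t]
        # stack all (feature, draw) permutations into one predict call
        n_blocks = len(varying) * draws
        stacked = np.tile(x_oob, (n_blocks, 1))
        for b, k in enumerate(np.repeat(varying, draws)):
            rows = slice(b * oob.size, (b + 1) * oob.size)
            stacked[rows, k] = x_oob[rng.permutation(oob.size), k]
        pred = tree.predict(stacked).reshape(len(varying), draws, oob.size)
        if is_classifier:
            err2 = (pred != t_oob[None, None, :]).mean(axis=(1, 2))
        else:
            err2 = ((pred - t_oob[None, None, :]) ** 2).mean(axis=(1, 2))
        vim_sum[varying] += err2 - base
    if used == 0:
        raise ValueError("no tree has a non-empty OOB set")
    return vim_sum / used


@dataclass
class VariableSelectionResult:
    """Replicate-averaged importances and the nested-selection outcome."""

    mean_vim: pd.Series
    threshold: float
    interpretation_set: list
    prediction_set: list
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_variables(
    X,
    y,
    feature_names=None,
    ntree: int = 500,
    mtry: int | None = None,
    n_perm: int = 1000,
    n_replicates: int = 25,
    n_eval: int = 5,
    seed: int = 0,
) -> VariableSelectionResult:
    """Heuristic noise-thresholded variable selection over RF importances.

    (1) features are ranked by mean permutation VIM over
    ``n_replicates`` independently seeded forests; (2) a data-derived
    noise threshold — mean + 2 SD of the magnitudes of negative-VIM
    features, or the minimum positive mean VIM if none are negative —
    keeps the interpretation set; (3) a nested forward pass over the
    ranked interpretation set records OOB AUC per prefix, and the
    prediction set is the smallest prefix whose AUC is within one
    standard error of the best.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    feature_names = list(feature_names)

    vims = np.zeros((n_replicates, p))
    for r in range(n_replicates):
        forest = BalancedRandomForestClassifier(
            ntree=ntree, mtry=mtry, random_state=seed + 1000 * r
        ).fit(X, y)
        vims[r] = permutation_vim(forest, X, n_perm=n_perm, seed=seed + 1000 * r + 1)
    mean_vim = pd.Series(vims.mean(axis=0), index=feature_names).sort_values(ascending=False)

    neg = mean_vim[mean_vim < 0].abs()
    if len(neg):
        threshold = float(neg.mean() + 2.0 * (neg.std(ddof=0) if len(neg) > 1 else 0.0))
    else:
        threshold = float(mean_vim[mean_vim > 0].min())
    interp = mean_vim[(mean_vim > 0) & (mean_vim >= threshold)].index.tolist()
    if not interp:
        warnings.warn("no feature exceeds the noise threshold; selection is empty")
        return VariableSelectionResult(mean_vim, threshold, [], [])

    order = [feature_names.index(f) for f in interp]
    rows = []
    auc_by_prefix = []
    for size in range(1, len(order) + 1):
        cols = order[:size]
        aucs = []
        for r in range(n_eval):
            forest = BalancedRandomForestClassifier(
                ntree=ntree, mtry=max(1, len(cols) // 2),
                random_state=seed + 7000 + 31 * size + r,
            ).fit(X[:, cols], y)
            aucs.append(oob_performance(forest)["auc"])
        auc_by_prefix.append(np.asarray(aucs))
        rows.append({"size": size, "auc_mean": float(np.mean(aucs)),
                     "auc_sd": float(np.std(aucs, ddof=1)) if n_eval > 1 else 0.0})
    trace = pd.DataFrame(rows).set_index("size")
    best = int(trace["auc_mean"].idxmax())
    se_best = float(np.std(auc_by_prefix[best - 1], ddof=1) / np.sqrt(n_eval)) if n_eval > 1 else 0.0
    ok = trace.index[trace["auc_mean"] >= trace.loc[best, "auc_mean"] - se_best]
    pred_size = int(ok.min())
    prediction = interp[:pred_size]
    return VariableSelectionResult(mean_vim, threshold, interp, prediction, trace)


@dataclass
class DriverRanking:
    """Which clinical parameter best predicts each gene's expression."""

    top_parameter: pd.Series  # per gene
    top_counts: pd.Series  # parameter -> number of genes topped
    single_parameter_auc: dict  # parameter -> OOB AUC for MHO classification
    combined_auc: float
    excluded: list


def rank_metabolic_drivers(
    expression,
    clinical: pd.DataFrame,
    labels,
    parameters=("hscrp", "tg_hdl", "glucose", "homa_ir"),
    ntree: int = 1000,
    n_perm: int = 200,
    seed: int = 0,
) -> DriverRanking:
    """Nested RF analysis of the metabolic drivers of module expression.

    (a) For every gene (row of ``expression``, genes x samples) an RF
    regression of its profile on the clinical parameters ranks the
    parameters by permutation VIM; the top parameter per gene is
    tabulated.  (b) MHO status is classified from each parameter alone
    and from all parameters jointly, reporting OOB AUC per model.
    Constant or duplicated parameters are excluded with a warning.
    """
    expr = (
        expression.to_numpy(dtype=float)
        if isinstance(expression, pd.DataFrame)
        else np.atleast_2d(np.asarray(expression, dtype=float))
    )
    gene_ids = (
        list(expression.index) if isinstance(expression, pd.DataFrame)
        else [f"g{i}" for i in range(expr.shape[0])]
    )
    missing = [p for p in parameters if p not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks parameter(s): {missing}")
    kept, excluded = [], []
    for p_name in parameters:
        col = clinical[p_name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"parameter {p_name!r} is constant; excluded")
            excluded.append(p_name)
            continue
        if any(np.allclose(col, clinical[q].to_numpy(dtype=float)) for q in kept):
            warnings.warn(f"parameter {p_name!r} duplicates another; excluded")
            excluded.append(p_name)
            continue
        kept.append(p_name)
    if not kept:
        raise ValueError("no usable clinical parameters")
    Xc = clinical[kept].to_numpy(dtype=float)

    top = {}
    for g, gene in enumerate(gene_ids):
        reg = OOBForestRegressor(
            ntree=ntree, mtry=max(1, len(kept) // 2), random_state=seed + g
        ).fit(Xc, expr[g])
        vim = permutation_vim(reg, Xc, n_perm=n_perm, seed=seed + g)
        top[gene] = kept[int(np.argmax(vim))]
    top_series = pd.Series(top)
    counts = top_series.value_counts().reindex(kept, fill_value=0)

    y = np.asarray(labels)
    single_auc = {}
    for j, p_name in enumerate(kept):
        forest = BalancedRandomForestClassifier(
            ntree=ntree, mtry=1, random_state=seed + 31 * j
        ).fit(Xc[:, [j]], y)
        single_auc[p_name] = oob_performance(forest)["auc"]
    forest = BalancedRandomForestClassifier(
        ntree=ntree, mtry=max(1, len(kept) // 2), random_state=seed + 997
    ).fit(Xc, y)
    combined = oob_performance(forest)["auc"]
    return DriverRanking(top_series, counts, single_auc, combined, excluded)
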