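"""Negative-binomial differential expression with likelihood-ratio tests.

Counts are modelled per gene as NB(mu, phi) with log link and offsets
equal to log effective library sizes.  Dispersions are estimated with a
two-level scheme: a common dispersion maximizing the summed Cox-Reid
adjusted profile likelihood (APL) across genes, and tagwise dispersions
maximizing each gene's APL plus ``prior_df`` residual-df worth of the
shared average APL (weighted-likelihood shrinkage toward common).  The
group effect is tested by a likelihood-ratio test of nested GLMs
(chi-square, 1 df) with BH FDR control; genes with |log2FC| > 0 and
q <= 0.05 are flagged differentially expressed.  A deviance
goodness-of-fit screen flags genes whose NB fit is poor, and a
PROPER-style simulation estimates detection power by fold-change and
expression stratum.  ddCt arithmetic for qPCR validation is included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._glm import adjusted_profile_loglik, fit_nb_glm, nb_deviance
from .preprocess import NormalizationResult, log_cpm, normalize
from .simulate import simulate_nb_counts

__all__ = [
    "DispersionModel",
    "estimate_dispersions",
    "nb_lrt_test",
    "gof_deviance",
    "power_simulation",
    "ddct_relative_expression",
    "NBDifferentialExpression",
]

_DEFAULT_GRID = np.logspace(-6, 1, 36)


@dataclass
class DispersionModel:
    """Common + tagwise NB dispersions with shrinkage metadata."""

    common: float
    tagwise: np.ndarray
    prior_df: float
    grid: np.ndarray

    def __post_init__(self):
        if self.common < 0 or np.any(self.tagwise < 0):
            raise ValueError("dispersions must be non-negative")


def _counts_to_array(counts) -> tuple[np.ndarray, object]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    return arr, pd.RangeIndex(arr.shape[0])


def _interp_argmax(logphi: np.ndarray, values: np.ndarray) -> float:
    """Parabolic refinement of a grid argmax (1-d)."""
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        return float(logphi[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(logphi[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    step = logphi[i + 1] - logphi[i]
    return float(logphi[i] + shift * step)


def _build_design(group: np.ndarray, covariates=None) -> tuple[np.ndarray, np.ndarray]:
    n = len(group)
    cols = [np.ones(n), np.asarray(group, dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    full = np.column_stack(cols)
    reduced = np.delete(full, 1, axis=1)
    return full, reduced


def estimate_dispersions(
    counts,
    design: np.ndarray,
    offset: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray = _DEFAULT_GRID,
) -> DispersionModel:
    """Common and tagwise NB dispersions via adjusted profile likelihood.

    ``design`` is the full model matrix (shared by all genes).  Requires
    residual degrees of freedom (more samples than coefficients).
    """
    y, _ = _counts_to_array(counts)
    n = y.shape[1]
    p = design.shape[1]
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no replication: dispersion is unidentifiable")
    if offset is None:
        offset = np.log(np.maximum(y.sum(axis=0), 1.0))
    usable = y.sum(axis=1) > 0
    logphi = np.log(grid)
    apl = np.full((y.shape[0], len(grid)), np.nan)
    for j, phi in enumerate(grid):
        apl[usable, j] = adjusted_profile_loglik(y[usable], design, offset, phi)
    mean_apl = np.nanmean(apl[usable], axis=0)
    common = float(np.exp(_interp_argmax(logphi, mean_apl)))

    prior_n = prior_df / df_resid
    weighted = apl + prior_n * mean_apl[None, :]
    tagwise = np.full(y.shape[0], common)
    for g in np.flatnonzero(usable):
        tagwise[g] = float(np.exp(_interp_argmax(logphi, weighted[g])))
    return DispersionModel(common=common, tagwise=tagwise, prior_df=prior_df, grid=grid)


def gof_deviance(y: np.ndarray, mu: np.ndarray, phi, df_resid: int) -> np.ndarray:
    """Upper-tail chi-square p-value of the residual deviance per gene."""
    if df_resid <= 0:
        return np.full(np.atleast_2d(y).shape[0], np.nan)
    dev = nb_deviance(y, mu, phi)
    return stats.chi2.sf(dev, df_resid)


def nb_lrt_test(
    counts,
    group,
    covariates=None,
    dispersions: DispersionModel | np.ndarray | float | None = None,
    normalization: NormalizationResult | None = None,
    prior_df: float = 10.0,
    fdr: float = 0.05,
    gof_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test of the group effect.

    ``group`` is binary with the reference coded 0 (MAO) so log2FC > 0
    means higher expression in the non-reference (MHO) group.  Offsets
    are log effective library sizes (TMM-scaled when ``normalization``
    is given).  Returns a data frame with log2FC, average log2-CPM,
    dispersion, LR statistic, p, BH q, deviance-GOF p and the DE flag
    (|log2FC| > 0 and q <= ``fdr``).  All-zero genes get NA rows.
    """
    y, gene_index = _counts_to_array(counts)
    group = np.asarray(group, dtype=float)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group must be binary 0/1 with the reference coded 0")
    full, reduced = _build_design(group, covariates)
    n = y.shape[1]
    if normalization is None:
        eff_lib = y.sum(axis=0)
    else:
        eff_lib = normalization.effective_libsizes
    offset = np.log(np.maximum(eff_lib, 1e-8))

    if dispersions is None:
        dispersions = estimate_dispersions(y, full, offset, prior_df=prior_df)
    if isinstance(dispersions, DispersionModel):
        phi = dispersions.tagwise
    else:
        phi = np.broadcast_to(np.asarray(dispersions, dtype=float), (y.shape[0],))

    usable = y.sum(axis=1) > 0
    res = pd.DataFrame(
        index=gene_index,
        columns=["log2FC", "avg_log2CPM", "dispersion", "LR", "pvalue", "qvalue",
                 "gof_p", "de_flag"],
        dtype=float,
    )
    res["dispersion"] = np.asarray(phi, dtype=float)
    norm = NormalizationResult(eff_lib / y.sum(axis=0), y.sum(axis=0))
    res["avg_log2CPM"] = np.asarray(log_cpm(y, norm)).mean(axis=1)

    if usable.any():
        fit_full = fit_nb_glm(y[usable], full, offset, phi[usable])
        fit_red = fit_nb_glm(y[usable], reduced, offset, phi[usable])
        if not fit_full["converged"].all():
            warnings.warn(
                f"{(~fit_full['converged']).sum()} gene(s) did not converge; "
                "their statistics are set to NA"
            )
        lr = np.maximum(2.0 * (fit_full["loglik"] - fit_red["loglik"]), 0.0)
        pvals = stats.chi2.sf(lr, df=1)
        ok = fit_full["converged"] & fit_red["converged"]
        lr[~ok] = np.nan
        pvals[~ok] = np.nan
        rows = np.flatnonzero(usable)
        res.iloc[rows, res.columns.get_loc("log2FC")] = fit_full["beta"][:, 1] / np.log(2.0)
        res.iloc[rows, res.columns.get_loc("LR")] = lr
        res.iloc[rows, res.columns.get_loc("pvalue")] = pvals
        res.iloc[rows, res.columns.get_loc("gof_p")] = gof_deviance(
            y[usable], fit_full["mu"], phi[usable], n - full.shape[1]
        )
    res.loc[~usable, ["log2FC", "LR", "pvalue", "gof_p"]] = np.nan

    mask = res["pvalue"].notna()
    res["qvalue"] = np.nan
    if mask.any():
        res.loc[mask, "qvalue"] = multipletests(res.loc[mask, "pvalue"], method="fdr_bh")[1]
    res["de_flag"] = (res["log2FC"].abs() > 0) & (res["qvalue"] <= fdr)
    res["gof_outlier"] = res["gof_p"] <= gof_threshold
    return res


def power_simulation(
    n_per_group: int = 8,
    lfc_grid=(0.14, 0.5, 1.0),
    mean_strata=(20.0, 80.0, 500.0),
    dispersion: float = 0.1,
    fdr: float = 0.15,
    n_sims: int = 5,
    genes_per_cell: int = 50,
    null_genes: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based power to detect DE by |log2FC| x mean stratum.

    Each replicate simulates ``genes_per_cell`` truly-DE genes for every
    (lfc, mean) cell plus ``null_genes`` null genes, runs dispersion
    estimation and the LRT, and scores the fraction of truly-DE genes
    with q <= ``fdr``.
    """
    rng = np.random.default_rng(seed)
    group = np.concatenate([np.zeros(n_per_group), np.ones(n_per_group)])
    cells = [(lfc, m) for lfc in lfc_grid for m in mean_strata]
    hits = {cell: [] for cell in cells}
    for _ in range(n_sims):
        means, true_de = [], []
        for lfc, m in cells:
            base = np.full((genes_per_cell, 2 * n_per_group), m, dtype=float)
            base[:, group == 1] *= 2.0**lfc
            means.append(base)
            true_de.extend([(lfc, m)] * genes_per_cell)
        null_means = rng.uniform(
            min(mean_strata), max(mean_strata), size=null_genes
        )[:, None] * np.ones((1, 2 * n_per_group))
        means.append(null_means)
        true_de.extend([None] * null_genes)
        mean_mat = np.vstack(means)
        y = simulate_nb_counts(mean_mat, dispersion, rng)
        res = nb_lrt_test(y, group, normalization=normalize(y))
        detected = res["qvalue"].to_numpy() <= fdr
        for cell in cells:
            idx = [i for i, c in enumerate(true_de) if c == cell]
            hits[cell].append(float(np.nanmean(detected[idx])))
    rows = [
        {"log2fc": lfc, "mean": m, "power": float(np.mean(hits[(lfc, m)]))}
        for lfc, m in cells
    ]
    return pd.DataFrame(rows)


def ddct_relative_expression(ct_target, ct_refs, groups, case=1, control=0) -> dict:
    """qPCR ddCt fold change between groups, normalized to reference genes.

    dCt = Ct_target - mean(Ct_refs) per sample (arithmetic mean across
    references); ddCt = mean dCt(case) - mean dCt(control); fold change
    = 2^-ddCt (amplification efficiency fixed at 2).
    """
    ct_target = np.asarray(ct_target, dtype=float)
    refs = np.asarray(ct_refs, dtype=float)
    if refs.ndim == 1:
        refs = refs[:, None]
    if refs.shape[0] != ct_target.shape[0]:
        raise ValueError("reference Cts must align with target Cts per sample")
    if refs.shape[1] < 1:
        raise ValueError("need at least one reference gene")
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(refs))):
        raise ValueError("Ct values must be finite")
    groups = np.asarray(groups)
    case_mask = groups == case
    ctrl_mask = groups == control
    if not case_mask.any() or not ctrl_mask.any():
        raise ValueError("both groups must contain at least one sample")
    dct = ct_target - refs.mean(axis=1)
    ddct = dct[case_mask].mean() - dct[ctrl_mask].mean()
    return {"delta_ct": dct, "delta_delta_ct": float(ddct),
            "fold_change": float(2.0**-ddct)}


class NBDifferentialExpression(BaseEstimator):
    """sklearn-style wrapper: fit NB LRT differential expression.

    ``fit(X, y)`` takes a samples x genes count matrix and a binary
    group vector (reference coded 0); results land in ``results_`` and
    the dispersion model in ``dispersions_``.
    """

    def __init__(self, prior_df: float = 10.0, fdr: float = 0.05,
                 gof_threshold: float = 0.01):
        self.prior_df = prior_df
        self.fdr = fdr
        self.gof_threshold = gof_threshold

    def fit(self, X, y, covariates=None):
        counts = np.asarray(X, dtype=float).T
        group = np.asarray(y, dtype=float)
        full, _ = _build_design(group, covariates)
        offset = np.log(np.maximum(counts.sum(axis=0), 1e-8))
        self.dispersions_ = estimate_dispersions(
            counts, full, offset, prior_df=self.prior_df
        )
        self.results_ = nb_lrt_test(
            counts, group, covariates=covariates, dispersions=self.dispersions_,
            prior_df=self.prior_df, fdr=self.fdr, gof_threshold=self.gof_threshold,
        )
        return self
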