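"""Count-matrix normalization and QC.

Counts are normalized between samples with the weighted trimmed mean of
M-values (TMM): per-gene log ratios against a reference sample are
doubly trimmed (30% on M, 5% on A) and averaged with inverse
asymptotic-variance weights; 2^that mean is the sample's scaling factor,
rescaled so factors have geometric mean 1.  Genes below 1 CPM in fewer
than 3 samples are removed before any analysis, and PCA on log-CPM flags
sample outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "pca_outliers",
    "NormalizationResult",
    "normalize",
    "TMMNormalizer",
    "LowExpressionFilter",
    "PCAOutlierDetector",
]


def _as_matrix(counts) -> tuple[np.ndarray, object, object]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index, counts.columns
    arr = np.asarray(counts, dtype=float)
    return arr, None, None


def _wrap(values, index, columns):
    if index is None and columns is None:
        return values
    return pd.DataFrame(values, index=index, columns=columns)


def compute_cpm(counts, effective_libsizes=None):
    """Counts per million: count / library size * 1e6, per column."""
    x, idx, cols = _as_matrix(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=0) if effective_libsizes is None else np.asarray(effective_libsizes, float)
    if np.any(lib <= 0):
        bad = np.flatnonzero(lib <= 0)
        names = [str(cols[i]) if cols is not None else str(i) for i in bad]
        raise ValueError(f"zero or negative library size for sample(s): {', '.join(names)}")
    return _wrap(x / lib[None, :] * 1e6, idx, cols)


def filter_low_expression(counts, min_cpm: float = 1.0, min_samples: int = 3):
    """Keep genes with CPM >= min_cpm in >= min_samples samples (inclusive).

    CPM here is computed on raw library sizes (pre-normalization); gene
    order is preserved.  May return an empty matrix (with a warning).
    """
    cpm, _, _ = _as_matrix(compute_cpm(counts))
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    if isinstance(counts, pd.DataFrame):
        return counts.loc[keep]
    return np.asarray(counts)[keep]


def _tmm_pair(obs, ref, lib_obs, lib_ref, logratio_trim, abs_trim, a_cutoff):
    """TMM factor of one sample against the reference (log2 scale -> 2^f)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        warnings.warn("no genes usable for TMM; factor set to 1")
        return 1.0
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # inverse asymptotic variance of M (delta method, binomial sampling)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        warnings.warn("all genes trimmed in TMM; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("all genes trimmed in TMM; factor set to 1")
        return 1.0
    f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
    ref_column=None,
) -> np.ndarray:
    """Weighted trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the column whose upper-quartile CPM is
    closest to the mean upper quartile; factors are rescaled to
    geometric mean 1.
    """
    x, _, _ = _as_matrix(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    if ref_column is None:
        uq = np.quantile(x / lib[None, :], 0.75, axis=0)
        ref_column = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_column], lib[j], lib[ref_column],
                      logratio_trim, abs_trim, a_cutoff)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


@dataclass
class NormalizationResult:
    """TMM factors with the effective library sizes they imply."""

    factors: np.ndarray
    library_sizes: np.ndarray
    prior_count: float = 0.5

    @property
    def effective_libsizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


def normalize(counts, **kwargs) -> NormalizationResult:
    """Compute TMM factors and package them with the raw library sizes."""
    x, _, _ = _as_matrix(counts)
    return NormalizationResult(tmm_factors(counts, **kwargs), x.sum(axis=0))


def log_cpm(counts, normalization: NormalizationResult | None = None, prior_count: float = 0.5):
    """log2 CPM with a small prior: log2((y + p) / (L_eff + 2p) * 1e6).

    Monotone in the count; with no normalization the raw library sizes
    are used.
    """
    x, idx, cols = _as_matrix(counts)
    if normalization is None:
        eff = x.sum(axis=0)
    else:
        eff = normalization.effective_libsizes
    vals = np.log2((x + prior_count) / (eff[None, :] + 2 * prior_count) * 1e6)
    return _wrap(vals, idx, cols)


def pca_outliers(logcpm, n_pcs: int = 2, sd_threshold: float = 3.0) -> np.ndarray:
    """Flag samples far from the cohort centroid in top-PC space.

    Each of the top ``n_pcs`` sample scores is standardized robustly
    (median / 1.4826*MAD); a sample is flagged when its Euclidean
    distance from the centroid in that standardized space exceeds
    ``sd_threshold * sqrt(n_pcs)`` — more than ``sd_threshold`` robust
    SDs per component.  Returns a boolean array per sample.
    """
    x, _, cols = _as_matrix(logcpm)
    n = x.shape[1]
    if n < 3:
        raise ValueError("PCA outlier detection needs at least 3 samples")
    if n_pcs >= n:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n - 1} (only {n} samples)")
        n_pcs = n - 1
    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x.T)
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    mad[mad == 0] = np.std(scores, axis=0)[mad == 0] + 1e-12
    z = (scores - med) / mad
    d = np.sqrt((z**2).sum(axis=1))
    # norm of the robust z-scores; the sqrt(n_pcs) factor makes the rule mean
    # "more than sd_threshold robust SDs per component", calibrated in n_pcs
    return d > sd_threshold * np.sqrt(n_pcs)


# ---------------------------------------------------------------------------
# sklearn-style wrappers (samples x genes orientation, sklearn convention)


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Drop genes (features) below ``min_cpm`` CPM in < ``min_samples`` samples."""

    def __init__(self, min_cpm: float = 1.0, min_samples: int = 3):
        self.min_cpm = min_cpm
        self.min_samples = min_samples

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        cpm = np.asarray(compute_cpm(X.T))
        self.support_ = (cpm >= self.min_cpm).sum(axis=1) >= self.min_samples
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """TMM-normalized log2-CPM transform for count matrices (samples x genes)."""

    def __init__(self, prior_count: float = 0.5, logratio_trim: float = 0.3,
                 abs_trim: float = 0.05):
        self.prior_count = prior_count
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.factors_ = tmm_factors(
            X.T, logratio_trim=self.logratio_trim, abs_trim=self.abs_trim
        )
        self.library_sizes_ = X.sum(axis=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "factors_")
        norm = NormalizationResult(self.factors_, self.library_sizes_, self.prior_count)
        return np.asarray(log_cpm(np.asarray(X, dtype=float).T, norm, self.prior_count)).T


class PCAOutlierDetector(OutlierMixin, BaseEstimator):
    """Flag outlying samples in top-principal-component space."""

    def __init__(self, n_pcs: int = 2, sd_threshold: float = 3.0):
        self.n_pcs = n_pcs
        self.sd_threshold = sd_threshold

    def fit(self, X, y=None):
        flags = pca_outliers(np.asarray(X, dtype=float).T, self.n_pcs, self.sd_threshold)
        self.outlier_mask_ = flags
        return self

    def fit_predict(self, X, y=None):
        # sklearn convention: -1 outlier, +1 inlier
        self.fit(X)
        return np.where(self.outlier_mask_, -1, 1)
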