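"""Weighted co-expression network construction and module detection.

The network is built from pairwise Pearson correlations s_ij between
gene expression profiles, soft-thresholded into an unsigned weighted
adjacency a_ij = |s_ij|^beta.  The soft power beta is chosen as the
smallest candidate whose degree distribution is approximately scale
free, P(k) ~ k^-gamma, operationalized as R^2 >= 0.8 of the log-log
regression of binned degree frequencies on degree (with a negative
slope required).  Genes are clustered by average-linkage (UPGMA)
hierarchical clustering on 1 - TOM, where TOM is the topological
overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

a similarity that rewards shared network neighborhoods.  Branches with
fewer than ``min_module_size`` genes remain unassigned (label 0), and
modules whose eigengenes are highly correlated are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "similarity_matrix",
    "soft_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "cluster_modules",
    "merge_modules",
    "ModulePartition",
    "ScaleFreeFitError",
    "CoexpressionNetwork",
]


class ScaleFreeFitError(RuntimeError):
    """No candidate power reached the required scale-free fit."""

    def __init__(self, message: str, fit_curve: pd.DataFrame):
        super().__init__(message)
        self.fit_curve = fit_curve


def similarity_matrix(logcpm) -> np.ndarray:
    """Pearson correlation between gene profiles (genes x samples input)."""
    if isinstance(logcpm, pd.DataFrame):
        x = logcpm.to_numpy(dtype=float)
    else:
        x = np.asarray(logcpm, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(logcpm.index[i]) for i in bad[:10]]
            if isinstance(logcpm, pd.DataFrame)
            else [str(i) for i in bad[:10]]
        )
        raise ValueError(f"zero-variance gene(s): {', '.join(names)}")
    s = np.corrcoef(x)
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def soft_adjacency(s: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned power adjacency |s|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(np.asarray(s, dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(a: np.ndarray) -> np.ndarray:
    """Weighted degree k_i = sum_{j != i} a_ij."""
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(a: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of an adjacency matrix.

    Degrees are binned into ``n_bins`` equal-width bins; the fit index is
    the R^2 of regressing log10(mean frequency) on log10(mean degree)
    over non-empty bins, forced to 0 when the slope is non-negative.
    """
    k = connectivity(np.asarray(a, dtype=float))
    return scale_free_fit_from_connectivity(k, n_bins=n_bins)


def scale_free_fit_from_connectivity(k: np.ndarray, n_bins: int = 10) -> float:
    k = np.asarray(k, dtype=float)
    distinct = np.unique(k)
    if distinct.size < 2:
        warnings.warn("all connectivities equal; scale-free fit undefined, returning 0")
        return 0.0
    if distinct.size < n_bins:
        n_bins = distinct.size
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if np.any(which == b) else np.nan for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 usable degree bins; returning 0")
        return 0.0
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    if slope >= 0:
        return 0.0
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(max(0.0, min(1.0, r2)))


def pick_soft_threshold(
    s: np.ndarray,
    candidate_powers=range(1, 21),
    fit_required: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power reaching the required scale-free fit.

    Returns (beta, fit curve); the curve holds the fit index, mean and
    maximum connectivity at every candidate.  Raises
    :class:`ScaleFreeFitError` (carrying the curve) if no candidate
    qualifies.
    """
    candidates = list(candidate_powers)
    if not candidates:
        raise ValueError("candidate power set is empty")
    abs_s = np.abs(np.asarray(s, dtype=float))
    rows = []
    chosen = None
    for beta in candidates:
        a = abs_s**beta
        np.fill_diagonal(a, 1.0)
        k = connectivity(a)
        fit = scale_free_fit_from_connectivity(k, n_bins=n_bins)
        rows.append({"power": beta, "fit": fit, "mean_k": k.mean(), "max_k": k.max()})
        if chosen is None and fit >= fit_required:
            chosen = beta
            # keep evaluating remaining powers so the full curve is reported
    curve = pd.DataFrame(rows).set_index("power")
    if chosen is None:
        raise ScaleFreeFitError(
            f"no candidate power reached fit index {fit_required}", curve
        )
    return chosen, curve


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Unsigned TOM: shared-neighbor-augmented adjacency, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-9:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = connectivity(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0  # sum_u a_iu a_uj, u ranging over all nodes
    # remove u in {i, j}: subtract a_ii*a_ij + a_ij*a_jj terms (a0 diag is 0
    # already, so only the u==i and u==j terms via a0 are absent by design)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModulePartition:
    """Gene-to-module assignment (0 = unassigned), sizes and merge history."""

    labels: np.ndarray
    gene_ids: list | None = None
    linkage: np.ndarray | None = None
    merge_history: list = field(default_factory=list)

    @property
    def module_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def genes_in(self, module: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == module)
        if self.gene_ids is not None:
            return np.asarray([self.gene_ids[i] for i in idx])
        return idx


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Make module labels contiguous, 1..K ordered by size descending."""
    out = np.zeros_like(labels)
    vals, counts = np.unique(labels[labels > 0], return_counts=True)
    order = vals[np.argsort(-counts, kind="stable")]
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def cluster_modules(
    tom: np.ndarray,
    min_module_size: int = 10,
    cut_height: float = 0.95,
    gene_ids=None,
) -> ModulePartition:
    """UPGMA clustering of 1 - TOM with a static cut.

    Branches below ``cut_height`` form candidate modules; those smaller
    than ``min_module_size`` are left unassigned (label 0).  Labels are
    contiguous, ordered by module size descending.
    """
    tom = np.asarray(tom, dtype=float)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = raw.copy()
    for lab, count in zip(*np.unique(raw, return_counts=True)):
        if count < min_module_size:
            labels[raw == lab] = 0
    labels = _relabel_by_size(labels)
    if labels.max() == 0:
        warnings.warn("no branch reached the minimum module size; all genes unassigned")
    return ModulePartition(labels=labels, gene_ids=list(gene_ids) if gene_ids is not None else None,
                           linkage=z)


def merge_modules(
    logcpm,
    partition: ModulePartition,
    merge_cor: float = 0.75,
) -> ModulePartition:
    """Iteratively merge modules whose eigengenes correlate above ``merge_cor``.

    Eigengenes are recomputed after every merge; the merge history
    records (kept, absorbed, correlation) tuples.  Final labels are
    re-ordered by size.
    """
    from .association import module_eigengene  # local import avoids cycle at import time

    x = logcpm.to_numpy(dtype=float) if isinstance(logcpm, pd.DataFrame) else np.asarray(logcpm, float)
    labels = partition.labels.copy()
    history: list[tuple[int, int, float]] = []
    while True:
        modules = sorted(set(labels[labels > 0]))
        if len(modules) < 2:
            break
        eig = {m: module_eigengene(x[labels == m])[0] for m in modules}
        best = None
        for i, mi in enumerate(modules):
            for mj in modules[i + 1 :]:
                r = float(np.corrcoef(eig[mi], eig[mj])[0, 1])
                if r > merge_cor and (best is None or r > best[2]):
                    best = (mi, mj, r)
        if best is None:
            break
        mi, mj, r = best
        labels[labels == mj] = mi
        history.append((int(mi), int(mj), r))
    labels = _relabel_by_size(labels)
    return ModulePartition(
        labels=labels,
        gene_ids=partition.gene_ids,
        linkage=partition.linkage,
        merge_history=partition.merge_history + history,
    )


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Weighted co-expression network module detection, sklearn-style.

    ``fit(X)`` takes a samples x genes expression matrix (typically
    log-CPM), picks the soft power (unless ``beta`` is given), builds the
    TOM and clusters genes into modules.  Fitted attributes follow the
    sklearn trailing-underscore convention; ``labels_`` assigns each
    gene (feature) a module, 0 meaning unassigned.
    """

    def __init__(
        self,
        beta: int | None = None,
        fit_required: float = 0.8,
        candidate_powers: tuple = tuple(range(1, 21)),
        min_module_size: int = 10,
        cut_height: float = 0.95,
        merge_cor: float = 0.75,
        merge: bool = True,
    ):
        self.beta = beta
        self.fit_required = fit_required
        self.candidate_powers = candidate_powers
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_cor = merge_cor
        self.merge = merge

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        expr = X.T  # genes x samples
        s = similarity_matrix(expr)
        if self.beta is None:
            beta, curve = pick_soft_threshold(
                s, self.candidate_powers, fit_required=self.fit_required
            )
        else:
            beta = self.beta
            curve = None
        a = soft_adjacency(s, beta)
        tom = topological_overlap(a)
        part = cluster_modules(tom, self.min_module_size, self.cut_height)
        if self.merge:
            part = merge_modules(expr, part, self.merge_cor)
        self.similarity_ = s
        self.beta_ = beta
        self.fit_curve_ = curve
        self.adjacency_ = a
        self.tom_ = tom
        self.scale_free_fit_ = scale_free_fit(a)
        self.partition_ = part
        self.labels_ = part.labels
        return self
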