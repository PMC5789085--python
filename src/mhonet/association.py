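"""Module eigengenes, membership, gene significance and trait association.

A module eigengene (ME) is the first principal component of the
gene-standardized module submatrix across samples — the module's summary
expression profile.  Module membership MM = |cor(gene, ME)| measures how
central a gene is to its module; gene significance GS = |cor(gene,
trait)| measures its marginal association with the phenotype.  A module
is declared trait-associated only under a dual rule: (1) the
FDR-adjusted p-value of the eigengene-trait (partial) correlation is
<= 0.05, and (2) the correlation between MM and GS over the module's
member genes is positive with p <= 0.05 — hub genes of a biologically
plausible module should also be the most trait-correlated genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "module_eigengene",
    "module_eigengenes",
    "module_membership",
    "gene_significance",
    "module_trait_association",
    "hypergeometric_enrichment",
]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene in module")
    return (x - mu) / sd


def module_eigengene(module_expr) -> tuple[np.ndarray, float]:
    """First principal component of a module (genes x samples input).

    Returns (eigengene, variance explained).  The eigengene has unit
    variance and its sign is aligned so it correlates non-negatively
    with the module's mean standardized expression.
    """
    x = (
        module_expr.to_numpy(dtype=float)
        if isinstance(module_expr, pd.DataFrame)
        else np.asarray(module_expr, dtype=float)
    )
    if x.shape[0] < 2:
        raise ValueError("module must contain at least 2 genes")
    z = _standardize_rows(x)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    eig = (eig - eig.mean()) / eig.std(ddof=1)
    return eig, var_explained


def module_eigengenes(logcpm, labels) -> tuple[pd.DataFrame, dict[int, float]]:
    """Eigengene matrix (samples x modules) for every labeled module."""
    x = (
        logcpm.to_numpy(dtype=float)
        if isinstance(logcpm, pd.DataFrame)
        else np.asarray(logcpm, dtype=float)
    )
    labels = np.asarray(labels)
    cols = {}
    varexp = {}
    for m in sorted(set(labels[labels > 0].tolist())):
        eig, ve = module_eigengene(x[labels == m])
        cols[m] = eig
        varexp[m] = ve
    samples = logcpm.columns if isinstance(logcpm, pd.DataFrame) else range(x.shape[1])
    return pd.DataFrame(cols, index=samples), varexp


def module_membership(gene_profile, eigengene, signed: bool = False) -> float:
    """|cor(gene, eigengene)| in [0, 1] (signed value available on request)."""
    g = np.asarray(gene_profile, dtype=float)
    e = np.asarray(eigengene, dtype=float)
    if g.std() == 0 or e.std() == 0:
        raise ValueError("zero-variance profile in module membership")
    r = float(np.corrcoef(g, e)[0, 1])
    return r if signed else abs(r)


def gene_significance(gene_profile, trait) -> float:
    """|cor(gene, trait)|; point-biserial when the trait is binary."""
    g = np.asarray(gene_profile, dtype=float)
    t = np.asarray(trait, dtype=float)
    if t.std() == 0:
        raise ValueError("trait is constant")
    if g.std() == 0:
        raise ValueError("gene profile is constant")
    return abs(float(np.corrcoef(g, t)[0, 1]))


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _cor_pvalue(r: float, df: int) -> float:
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def module_trait_association(
    eigengenes: pd.DataFrame,
    trait,
    covariates=None,
    logcpm=None,
    labels=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Module-trait correlations with the dual significance rule.

    Each eigengene is correlated with the trait, partialling out the
    covariates (both sides residualized on an intercept + covariates);
    p-values come from the t-distribution with n - 2 - n_covariates
    degrees of freedom and are BH-adjusted across modules.  When the
    expression matrix and module labels are given, the MM-GS correlation
    over each module's member genes is added, and the ``significant``
    flag applies the dual rule: FDR q <= ``fdr`` AND MM-GS r > 0 with
    p <= 0.05.
    """
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    n_cov = cov.shape[1]
    t_resid = _residualize(trait, cov) if n_cov else trait
    if t_resid.std() <= 1e-10 * (np.abs(trait).max() + 1.0):
        raise ValueError("trait collinear with covariates")
    df = n - 2 - n_cov

    rows = []
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(dtype=float)
        e_resid = _residualize(e, cov) if n_cov else e
        r = float(np.corrcoef(e_resid, t_resid)[0, 1])
        rows.append({"module": m, "r": r, "p": _cor_pvalue(r, df)})
    res = pd.DataFrame(rows).set_index("module")
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]

    if logcpm is not None and labels is not None:
        x = (
            logcpm.to_numpy(dtype=float)
            if isinstance(logcpm, pd.DataFrame)
            else np.asarray(logcpm, dtype=float)
        )
        labels = np.asarray(labels)
        mmgs_r, mmgs_p = {}, {}
        for m in res.index:
            members = np.flatnonzero(labels == m)
            eig = eigengenes[m].to_numpy(dtype=float)
            mm = np.array([module_membership(x[i], eig) for i in members])
            gs = np.array([gene_significance(x[i], trait) for i in members])
            if len(members) < 3 or mm.std() == 0 or gs.std() == 0:
                mmgs_r[m], mmgs_p[m] = np.nan, np.nan
                continue
            r = float(np.corrcoef(mm, gs)[0, 1])
            mmgs_r[m] = r
            mmgs_p[m] = _cor_pvalue(r, len(members) - 2)
        res["mm_gs_r"] = pd.Series(mmgs_r)
        res["mm_gs_p"] = pd.Series(mmgs_p)
        res["significant"] = (
            (res["q"] <= fdr) & (res["mm_gs_r"] > 0) & (res["mm_gs_p"] <= 0.05)
        )
    return res


def hypergeometric_enrichment(
    module_genes,
    gene_sets: dict[str, list],
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Equivalent to a one-sided Fisher exact test: p = P(X >= overlap)
    for X ~ Hypergeom(universe size, set size in universe, module size).
    Gene sets are intersected with the universe; BH FDR across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    big_n, n_mod = len(universe), len(module)
    rows = []
    for name, genes in gene_sets.items():
        in_univ = set(genes) & universe
        k = len(in_univ & module)
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(in_univ),
                "module_size": n_mod,
                "universe_size": big_n,
                "p": float(stats.hypergeom.sf(k - 1, big_n, len(in_univ), n_mod)),
            }
        )
    res = pd.DataFrame(rows).set_index("gene_set")
    if len(res):
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    return res
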