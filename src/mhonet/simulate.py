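"""Seeded synthetic cohorts for the MHO co-expression pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised without any real download:

* negative-binomial read counts with per-gene baseline abundance,
  gamma-distributed dispersions and log-normal library-size variation;
* planted co-expression modules driven by Gaussian latent factors with
  gene-specific loadings (the minimal correlated-block structure a
  weighted co-expression network analysis assumes);
* one module whose latent factor is shifted *down* in MHO subjects, so
  the module is under-expressed in the healthy-obese group;
* clinical covariates drawn per group from log-normal distributions
  calibrated to the reference cohort summary (8 MHO vs 21 MAO), with the
  TG/HDL ratio coupled to the associated module's factor through a
  Gaussian copula so the driver-ranking stage has recoverable truth.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import MHO, REFERENCE_COHORT_SUMMARY, classify_cohort

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "resample_consistent_clinical",
    "simulate_nb_counts",
    "default_clinical_params",
]

#: Generator choices for covariates the reference table does not fully
#: specify: HDL-C (mg/dl, lognormal mean/sd), blood pressure (normal
#: mean/sd, truncated at the hypertension cutoffs for normotensives).
_HDL_PARAMS = {"MHO": (55.0, 12.0), "MAO": (48.0, 11.0)}
_BP_NORMO = {"sbp": (118.0, 7.0), "dbp": (74.0, 6.0)}
_BP_HYPER = {"sbp": (142.0, 10.0), "dbp": (92.0, 7.0)}

_CLINICAL_LOGNORMAL_VARS = ("glucose", "hscrp", "homa_ir", "tg_hdl")


def default_clinical_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (arithmetic mean, SD) for the log-normal clinical variables."""
    return {
        group: {var: REFERENCE_COHORT_SUMMARY[group][var] for var in _CLINICAL_LOGNORMAL_VARS}
        for group in ("MHO", "MAO")
    }


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("log-normal calibration needs positive mean and SD")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, float(np.sqrt(sigma2))


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic cohort.

    Defaults reproduce the study conditions: 8 MHO vs 21 MAO subjects,
    2,000 genes with three planted 50-gene modules, the first module's
    latent factor shifted down by ``assoc_effect`` standard deviations in
    MHO samples, and clinical covariates calibrated to the reference
    cohort summary.
    """

    n_mho: int = 8
    n_mao: int = 21
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (50, 50, 50)
    assoc_module_index: int = 0
    assoc_effect: float = 1.5
    loading_mean: float = 0.8
    loading_sd: float = 0.15
    baseline_logmean_range: tuple[float, float] = (1.0, 9.0)  # log2 counts
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.06
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.25
    tg_hdl_factor_cor: float = 0.6
    clinical_params: dict = field(default_factory=default_clinical_params)
    de_logfc: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mho, self.n_mao) < 1 or self.n_genes < 1:
            raise ValueError("group sizes and gene count must be positive")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) must not exceed n_genes")
        if self.module_sizes and not (
            0 <= self.assoc_module_index < len(self.module_sizes)
        ):
            raise ValueError("assoc_module_index out of range")
        if not np.isfinite(self.assoc_effect):
            raise ValueError("assoc_effect must be finite")
        if self.loading_sd <= 0 or self.libsize_logsd <= 0:
            raise ValueError("every sd must be positive")
        if self.dispersion_shape <= 0 or self.dispersion_scale <= 0:
            raise ValueError("dispersion hyper-parameters must be positive")
        if not -1 < self.tg_hdl_factor_cor < 1:
            raise ValueError("tg_hdl_factor_cor must be in (-1, 1)")
        if self.de_logfc is not None:
            self.de_logfc = np.asarray(self.de_logfc, dtype=float)
            if self.de_logfc.shape != (self.n_genes,):
                raise ValueError("de_logfc must have length n_genes")

    @property
    def n_samples(self) -> int:
        return self.n_mho + self.n_mao


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort (0 = background gene)."""

    module_labels: np.ndarray  # (n_genes,) int
    loadings: np.ndarray  # (n_genes,) float
    baselines: np.ndarray  # (n_genes,) log2 mean counts
    dispersions: np.ndarray  # (n_genes,) NB dispersion phi
    log2fc: np.ndarray  # (n_genes,) true MHO-vs-MAO log2 fold change
    factors: np.ndarray  # (n_samples, n_modules)
    group: np.ndarray  # (n_samples,) 1 = MHO
    gene_ids: list[str]
    sample_ids: list[str]
    seed: int

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.module_labels) if m == module]

    def to_json(self, path) -> None:
        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump(payload, fh)


def simulate_nb_counts(mean: np.ndarray, dispersion, rng: np.random.Generator) -> np.ndarray:
    """Draw NB counts with E=mean, Var=mean+phi*mean^2 (gamma-Poisson mixture).

    ``dispersion`` may be a scalar or broadcastable to ``mean``; zero
    dispersion falls back to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, phi[~pois] * mean[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def _truncated_normal(rng, mean, sd, upper=None, lower=None, size=None):
    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _draw_clinical_rows(
    config: SyntheticConfig,
    groups: np.ndarray,
    factor_z: np.ndarray,
    rng: np.random.Generator,
    rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw (or redraw) clinical covariates for the given subject rows.

    ``factor_z`` is the within-group standardized latent factor of the
    associated module; the TG/HDL ratio is coupled to it with correlation
    ``config.tg_hdl_factor_cor`` through a Gaussian copula.
    """
    n = len(groups)
    if rows is None:
        rows = np.arange(n)
    r = config.tg_hdl_factor_cor
    data: dict[str, np.ndarray] = {}
    group_names = np.where(groups == 1, "MHO", "MAO")

    sex = np.empty(n, dtype=object)
    age = np.empty(n)
    bmi = np.empty(n)
    sbp = np.empty(n)
    dbp = np.empty(n)
    bp_med = np.zeros(n, dtype=bool)
    smoker = np.zeros(n, dtype=bool)
    drinker = np.zeros(n, dtype=bool)
    lnvars = {v: np.empty(n) for v in _CLINICAL_LOGNORMAL_VARS}
    hdl = np.empty(n)

    for i in rows:
        g = group_names[i]
        ref = REFERENCE_COHORT_SUMMARY[g]
        sex[i] = "F" if rng.uniform() < ref["female_frac"] else "M"
        age[i] = rng.normal(*ref["age"])
        # BMI truncated at the obesity cutoff so every subject is obese
        mu, sigma = _lognormal_params(*ref["bmi"])
        lo = (np.log(30.0) - mu) / sigma
        bmi[i] = float(np.exp(stats.truncnorm.ppf(rng.uniform(), lo, np.inf, loc=mu, scale=sigma)))
        hypertensive = rng.uniform() < ref["hypertensive_frac"]
        bp = _BP_HYPER if hypertensive else _BP_NORMO
        if hypertensive:
            sbp[i] = rng.normal(*bp["sbp"])
            dbp[i] = rng.normal(*bp["dbp"])
            bp_med[i] = True
        else:
            sbp[i] = _truncated_normal(rng, *bp["sbp"], upper=130.0)
            dbp[i] = _truncated_normal(rng, *bp["dbp"], upper=85.0)
        smoker[i] = rng.uniform() < ref["smoker_frac"]
        drinker[i] = rng.uniform() < ref["drinker_frac"]
        for var in _CLINICAL_LOGNORMAL_VARS:
            mu, sigma = _lognormal_params(*config.clinical_params[g][var])
            if var == "tg_hdl":
                z = r * factor_z[i] + np.sqrt(1 - r * r) * rng.standard_normal()
            else:
                z = rng.standard_normal()
            lnvars[var][i] = float(np.exp(mu + sigma * z))
        mu, sigma = _lognormal_params(*_HDL_PARAMS[g])
        hdl[i] = float(np.exp(rng.normal(mu, sigma)))

    data.update(
        sex=sex,
        age=age,
        bmi=bmi,
        sbp=sbp,
        dbp=dbp,
        bp_medication=bp_med,
        glucose=lnvars["glucose"],
        homa_ir=lnvars["homa_ir"],
        hscrp=lnvars["hscrp"],
        tg_hdl=lnvars["tg_hdl"],
        hdl=hdl,
        smoker=smoker,
        drinker=drinker,
    )
    df = pd.DataFrame(data)
    df["tg"] = df["tg_hdl"] * df["hdl"]
    return df


def resample_consistent_clinical(
    clinical: pd.DataFrame,
    labels,
    config: SyntheticConfig,
    factor_z: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    max_rounds: int = 50,
) -> pd.DataFrame:
    """Redraw clinical rows until subjects classify back to their group.

    Subjects whose drawn covariates violate their assigned group under
    the default (most comprehensive) MHO definition are redrawn, up to
    ``max_rounds`` rounds; leftovers trigger a warning naming them.
    """
    labels = np.asarray(labels)
    groups = (labels == MHO).astype(int)
    if factor_z is None:
        factor_z = np.zeros(len(labels))
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    clinical = clinical.copy()
    for _ in range(max_rounds):
        assigned = classify_cohort(clinical, definition=3)["label"].to_numpy()
        bad = np.flatnonzero(assigned != labels)
        if bad.size == 0:
            return clinical
        redrawn = _draw_clinical_rows(config, groups, factor_z, rng, rows=bad)
        clinical.iloc[bad] = redrawn.iloc[bad][clinical.columns]
    assigned = classify_cohort(clinical, definition=3)["label"].to_numpy()
    bad = np.flatnonzero(assigned != labels)
    if bad.size:
        warnings.warn(
            "retry budget exhausted; inconsistent subjects: "
            + ", ".join(str(clinical.index[i]) for i in bad)
        )
    return clinical


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns
    -------
    counts : DataFrame, genes x samples
        NB read counts.
    clinical : DataFrame, samples x variables
        Covariates consistent with each subject's assigned group.
    truth : SyntheticTruth
        Planted structure for downstream validation.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    n_modules = len(config.module_sizes)

    group = np.concatenate([np.ones(config.n_mho, int), np.zeros(config.n_mao, int)])
    sample_ids = [
        f"{'MHO' if x else 'MAO'}_{i + 1:02d}"
        for x, i in zip(group, list(range(config.n_mho)) + list(range(config.n_mao)))
    ]
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]

    # planted module structure
    module_labels = np.zeros(g, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_labels[pos : pos + size] = m
        pos += size
    loadings = np.zeros(g)
    in_module = module_labels > 0
    loadings[in_module] = rng.normal(config.loading_mean, config.loading_sd, in_module.sum())

    baselines = rng.uniform(*config.baseline_logmean_range, size=g)
    dispersions = rng.gamma(config.dispersion_shape, config.dispersion_scale, size=g)
    libsize = np.exp(rng.normal(config.libsize_logmean, config.libsize_logsd, size=n))
    depth = libsize / np.exp(np.mean(np.log(libsize)))

    factors = rng.standard_normal((n, n_modules)) if n_modules else np.zeros((n, 0))
    if n_modules:
        # The associated module's factor is shifted down by exactly
        # assoc_effect in MHO subjects: its noise is centered within each
        # group first, so the realized standardized shift equals the
        # configured one instead of varying with the finite-sample draw.
        fa = factors[:, config.assoc_module_index]
        for grp in (0, 1):
            fa[group == grp] -= fa[group == grp].mean()
        factors[:, config.assoc_module_index] = fa - config.assoc_effect * group

    de_logfc = (
        np.zeros(g) if config.de_logfc is None else np.asarray(config.de_logfc, float)
    )
    log2_mean = baselines[:, None] + np.outer(de_logfc, group)
    for m in range(n_modules):
        mask = module_labels == m + 1
        log2_mean[mask] += np.outer(loadings[mask], factors[:, m])
    mean = np.exp2(log2_mean) * depth[None, :]
    counts = simulate_nb_counts(mean, dispersions[:, None], rng)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    # true group log2FC: direct planted effect plus the factor-mediated shift
    log2fc = de_logfc.copy()
    if n_modules:
        assoc_mask = module_labels == config.assoc_module_index + 1
        log2fc[assoc_mask] += -config.assoc_effect * loadings[assoc_mask]

    # within-group standardized associated factor, for the TG/HDL copula
    if n_modules:
        f = factors[:, config.assoc_module_index]
        factor_z = f + config.assoc_effect * group  # remove the group shift
    else:
        factor_z = np.zeros(n)

    labels = np.where(group == 1, "MHO", "MAO")
    clinical = _draw_clinical_rows(config, group, factor_z, rng)
    clinical.index = pd.Index(sample_ids, name="sample")
    clinical = resample_consistent_clinical(
        clinical, labels, config, factor_z=factor_z, rng=rng
    )
    clinical["group"] = labels

    truth = SyntheticTruth(
        module_labels=module_labels,
        loadings=loadings,
        baselines=baselines,
        dispersions=dispersions,
        log2fc=log2fc,
        factors=factors,
        group=group,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        seed=config.seed,
    )
    return counts_df, clinical, truth
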