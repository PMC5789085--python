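"""End-to-end orchestration of the three complementary strategies.

The full analysis runs, in order: cohort loading or simulation ->
normalization and QC -> phenotype classification -> co-expression
network module detection -> module-trait association (dual significance
rule) -> negative-binomial differential expression restricted to the
genes of trait-associated modules -> balanced random-forest
classification per associated module with permutation importance,
variable selection and metabolic driver ranking.  Every stage is a pure
function of (inputs, config, seed); identical configuration yields an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import module_eigengenes, module_trait_association
from .diffexpr import nb_lrt_test
from .forest import (
    BalancedRandomForestClassifier,
    oob_performance,
    permutation_vim,
    rank_metabolic_drivers,
    select_variables,
)
from .network import CoexpressionNetwork
from .phenotype import MHO, classify_cohort
from .preprocess import filter_low_expression, log_cpm, normalize, pca_outliers
from .simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger("mhonet")

__all__ = ["PipelineConfig", "run_full_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds and inputs of one full analysis run.

    Exactly one of ``simulate`` and (``counts_path``, ``clinical_path``)
    must be provided.
    """

    simulate: SyntheticConfig | None = None
    counts_path: str | None = None
    clinical_path: str | None = None
    definition: int = 3
    min_cpm: float = 1.0
    min_samples: int = 3
    min_module_size: int = 10
    fit_required: float = 0.8
    cut_height: float = 0.95
    merge_cor: float = 0.75
    fdr: float = 0.05
    rf_ntree: int = 10000
    rf_nperm: int = 1000
    rf_replicates: int = 25
    de_all_genes: bool = False
    run_variable_selection: bool = True
    run_driver_ranking: bool = True
    seed: int = 0

    def __post_init__(self):
        has_paths = self.counts_path is not None and self.clinical_path is not None
        if (self.simulate is None) == (not has_paths):
            raise ValueError("provide exactly one of a simulate block or input paths")
        for name in ("min_cpm", "fit_required", "cut_height", "merge_cor", "fdr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_full_analysis(config: PipelineConfig, out_dir=None) -> dict:
    """Run the whole pipeline and return a machine-readable report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    truth = None

    @_stage("load")
    def load():
        nonlocal truth
        if config.simulate is not None:
            counts, clinical, truth = generate_cohort(config.simulate)
            return counts, clinical
        from .io import read_clinical, read_counts

        return read_counts(config.counts_path), read_clinical(config.clinical_path)

    counts, clinical = load()

    @_stage("phenotype")
    def phenotype():
        lab = classify_cohort(clinical, definition=config.definition)
        return lab

    labels_df = phenotype()
    labels = labels_df["label"].to_numpy()
    trait = (labels == MHO).astype(int)
    if len(set(labels)) < 2:
        raise PipelineError("phenotype", "cohort contains a single phenotype group")
    sex_female = (clinical["sex"].astype(str).str.upper().str.startswith("F")).astype(float)

    @_stage("preprocess")
    def preprocess():
        filtered = filter_low_expression(counts, config.min_cpm, config.min_samples)
        norm = normalize(filtered)
        lcpm = log_cpm(filtered, norm)
        outliers = pca_outliers(lcpm)
        return filtered, norm, lcpm, outliers

    filtered, norm, lcpm, outliers = preprocess()
    keep_samples = ~outliers
    if outliers.any():
        # renormalize after dropping outlying samples
        filtered = filtered.loc[:, keep_samples]
        norm = normalize(filtered)
        lcpm = log_cpm(filtered, norm)
    trait = trait[keep_samples]
    sex_female = sex_female[keep_samples]
    clinical_kept = clinical.loc[keep_samples]
    report["qc"] = {
        "genes_input": int(counts.shape[0]),
        "genes_after_filter": int(filtered.shape[0]),
        "samples_input": int(counts.shape[1]),
        "outlier_samples": [str(s) for s in counts.columns[outliers]],
        "tmm_factors": norm.factors.tolist(),
    }

    @_stage("network")
    def network():
        net = CoexpressionNetwork(
            fit_required=config.fit_required,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cor=config.merge_cor,
        ).fit(lcpm.to_numpy().T)
        return net

    net = network()
    labels_genes = net.labels_
    report["network"] = {
        "beta": int(net.beta_),
        "scale_free_fit": float(net.fit_curve_.loc[net.beta_, "fit"]),
        "n_modules": int(net.partition_.n_modules),
        "module_sizes": {int(k): int(v) for k, v in net.partition_.module_sizes.items()},
    }

    @_stage("module_association")
    def association():
        eig, varexp = module_eigengenes(lcpm, labels_genes)
        stats = module_trait_association(
            eig, trait, covariates=sex_female.to_numpy(), logcpm=lcpm,
            labels=labels_genes, fdr=config.fdr,
        )
        return eig, varexp, stats

    eigengenes, varexp, mt_stats = association()
    assoc_modules = [int(m) for m in mt_stats.index[mt_stats["significant"]]]
    report["module_trait"] = json.loads(mt_stats.to_json(orient="index"))
    report["associated_modules"] = assoc_modules

    @_stage("diffexpr")
    def diffexpr():
        if config.de_all_genes:
            mask = np.ones(len(labels_genes), dtype=bool)
        else:
            mask = np.isin(labels_genes, assoc_modules)
        if not mask.any():
            return None
        # offsets must come from the full-matrix normalization: the module
        # genes are co-regulated, so their own column sums track the group
        # effect and would absorb the signal
        de = nb_lrt_test(
            filtered.loc[mask],
            trait,
            covariates=sex_female.to_numpy(),
            normalization=norm,
            fdr=config.fdr,
        )
        return de

    de = diffexpr()
    report["diffexpr"] = {
        "genes_tested": 0 if de is None else int(len(de)),
        "de_flagged": 0 if de is None else int(de["de_flag"].sum()),
    }

    @_stage("rf_classify")
    def rf():
        out_rf = {}
        for m in assoc_modules:
            genes = np.flatnonzero(labels_genes == m)
            X = lcpm.to_numpy()[genes].T
            forest = BalancedRandomForestClassifier(
                ntree=config.rf_ntree, random_state=config.seed
            ).fit(X, trait)
            perf = oob_performance(forest)
            vim = permutation_vim(forest, X, n_perm=config.rf_nperm, seed=config.seed)
            entry = {
                "performance": perf,
                "vim": dict(zip([str(lcpm.index[g]) for g in genes], vim.tolist())),
            }
            if config.run_variable_selection:
                sel = select_variables(
                    X, trait, feature_names=[str(lcpm.index[g]) for g in genes],
                    ntree=min(config.rf_ntree, 500), n_perm=config.rf_nperm,
                    n_replicates=config.rf_replicates, seed=config.seed,
                )
                entry["selection"] = {
                    "threshold": sel.threshold,
                    "interpretation_set": sel.interpretation_set,
                    "prediction_set": sel.prediction_set,
                }
            out_rf[int(m)] = entry
        return out_rf

    report["rf"] = rf()

    @_stage("driver_ranking")
    def drivers():
        if not assoc_modules or not config.run_driver_ranking:
            return None
        m = assoc_modules[0]
        genes = np.flatnonzero(labels_genes == m)
        ranking = rank_metabolic_drivers(
            lcpm.iloc[genes], clinical_kept, trait,
            ntree=min(config.rf_ntree, 1000), seed=config.seed,
        )
        return {
            "top_counts": ranking.top_counts.to_dict(),
            "single_parameter_auc": ranking.single_parameter_auc,
            "combined_auc": ranking.combined_auc,
        }

    report["drivers"] = drivers()

    if truth is not None:
        report["truth_available"] = True

    if out is not None:
        lcpm.to_csv(out / "logcpm.tsv", sep="\t")
        pd.Series(labels_genes, index=lcpm.index, name="module").to_csv(
            out / "modules.tsv", sep="\t"
        )
        mt_stats.to_csv(out / "module_trait.tsv", sep="\t")
        if de is not None:
            de.to_csv(out / "de.tsv", sep="\t")
        net.fit_curve_.to_csv(out / "fitcurve.tsv", sep="\t")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
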