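# mhonet

Transcriptomic signatures of metabolically healthy obesity.

Not all obese individuals develop insulin resistance, dyslipidemia or
chronic inflammation.  `mhonet` implements, as a tested and reusable
Python package, the whole-blood RNA-seq analysis pipeline used to ask
*which co-expressed gene programs separate metabolically healthy obese
(MHO) from metabolically abnormal obese (MAO) adults*: weighted gene
co-expression network analysis, module–trait association under a dual
significance rule, negative-binomial differential expression, and
balanced random-forest classification with permutation importance,
variable selection and metabolic driver ranking.  A calibrated
synthetic cohort generator provides ground truth for every stage, so
the whole pipeline is exercisable — and testable — without any data
download.  It is written for computational biologists who want either
the individual statistical building blocks (sklearn-style estimators
and plain functions) or the one-call pipeline.

## The model in brief

* **Phenotype.**  Obese subjects (BMI ≥ 30) are MHO when they meet,
  inclusively: BP ≤ 130/85 mmHg without medication, glucose ≤ 100
  mg/dl, HOMA-IR ≤ 5.1, TG/HDL ≤ 1.65 (M) / 1.32 (F), and hsCRP ≤ 0.3
  mg/dl; otherwise MAO.
* **Network.**  From log₂-CPM (TMM-normalized, low-expression genes
  removed), gene similarity s_ij = cor(x_i, x_j) is soft-thresholded
  into an unsigned adjacency a_ij = |s_ij|^β, with β the smallest
  power giving approximate scale-free topology (R² ≥ 0.8 of the
  log–log degree regression).  Genes are clustered by UPGMA on
  1 − TOM, where TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij);
  branches under 10 genes stay unassigned and similar modules are
  merged.
* **Association.**  A module's eigengene (first PC of its standardized
  expression) is correlated with MHO status, partialling out sex.  A
  module is significant only if FDR q ≤ 0.05 *and* the correlation
  between module membership MM = |cor(gene, eigengene)| and gene
  significance GS = |cor(gene, MHO)| over its members is positive with
  p ≤ 0.05.
* **Differential expression.**  Per-gene NB GLMs (log link, TMM
  offsets), common + tagwise Cox-Reid dispersion estimation with
  shrinkage, likelihood-ratio tests (χ², 1 df), BH FDR; DE means
  |log₂FC| > 0 and q ≤ 0.05.
* **Classification.**  Random forests with balanced per-tree
  bootstraps (equal draws per class), mtry = ⌊p/2⌋, OOB AUC /
  sensitivity / specificity, permutation variable importance, a
  VSURF-style selection of the smallest predictive gene subset, and
  nested RF regressions ranking which metabolic parameter (hsCRP,
  TG/HDL, glucose, HOMA-IR) drives module expression.

Full details, parameter tables and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from mhonet import (SyntheticConfig, generate_cohort, filter_low_expression,
                    log_cpm, CoexpressionNetwork, module_eigengenes,
                    module_trait_association, nb_lrt_test,
                    BalancedRandomForestClassifier, oob_performance)
from mhonet.preprocess import normalize

config = SyntheticConfig(seed=1)          # 8 MHO vs 21 MAO, 2,000 genes
counts, clinical, truth = generate_cohort(config)

filtered = filter_low_expression(counts)  # CPM >= 1 in >= 3 samples
norm = normalize(filtered)                # TMM factors
lcpm = log_cpm(filtered, norm)

net = CoexpressionNetwork().fit(lcpm.to_numpy().T)
print(f"soft power beta = {net.beta_}, scale-free fit = {net.scale_free_fit_:.3f}")
print(f"modules detected: {net.partition_.module_sizes}")

trait = (clinical["group"] == "MHO").astype(int).to_numpy()
sex = clinical["sex"].eq("F").astype(float).to_numpy()
eigengenes, _ = module_eigengenes(lcpm, net.labels_)
assoc = module_trait_association(eigengenes, trait, covariates=sex,
                                 logcpm=lcpm, labels=net.labels_)
print(assoc.round(3))

module = int(assoc.index[assoc["significant"]][0])
de = nb_lrt_test(filtered.loc[net.labels_ == module], trait,
                 covariates=sex, normalization=norm)
print(f"DE in module {module}: {int(de['de_flag'].sum())}/{len(de)} genes at q<=0.05, "
      f"median log2FC = {de['log2FC'].median():.2f}")

X = lcpm.to_numpy()[net.labels_ == module].T
forest = BalancedRandomForestClassifier(ntree=2000, random_state=1).fit(X, trait)
perf = oob_performance(forest)
print(f"balanced RF: OOB AUC = {perf['auc']:.2f}, error = {perf['oob_error']:.2f}, "
      f"sensitivity = {perf['sensitivity']:.2f}, specificity = {perf['specificity']:.2f}")
```

Output:

```
soft power beta = 4, scale-free fit = 0.803
modules detected: {1: 60, 2: 57, 3: 48}
            r      p      q  mm_gs_r  mm_gs_p  significant
module
1       0.113  0.566  0.566    0.055    0.675        False
2      -0.489  0.008  0.025    0.642    0.000         True
3       0.128  0.516  0.566   -0.101    0.495        False
DE in module 2: 33/57 genes at q<=0.05, median log2FC = -1.20
balanced RF: OOB AUC = 0.90, error = 0.21, sensitivity = 0.62, specificity = 0.86
```

Reading it: the power-selection rule lands on β = 4 with a scale-free
fit of 0.80; three co-expression modules are detected, matching the
three planted ones.  Module 2 — which holds the genes of the planted
MHO-associated module — is negatively correlated with MHO status after
adjusting for sex (r = −0.49, q = 0.025) and passes the dual rule
(MM–GS r = 0.64, p < 0.001): it is under-expressed in the healthy
obese group.  33 of its 57 genes are individually differentially
expressed with a negative median log₂ fold change, and a balanced
random forest on its genes classifies MHO with OOB AUC 0.90 despite
the 8-vs-21 imbalance.

The same flow runs end to end via `mhonet.run_full_analysis(PipelineConfig(...))`
or the CLI (`mhonet simulate / preprocess / phenotype / network /
associate / de / rf / power / run`).

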