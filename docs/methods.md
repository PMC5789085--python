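# Methods

`mhonet` implements a whole-blood transcriptomic analysis of
metabolically healthy obesity (MHO): weighted co-expression network
module detection, module–trait association under a dual significance
rule, negative-binomial differential expression, and balanced
random-forest classification, together with a synthetic cohort
generator that provides ground truth for every stage.

## Phenotype model

Obese subjects (BMI ≥ 30 kg/m²) are classified MHO or MAO
(metabolically abnormal obese) by rule sets of increasing stringency.
The pipeline default (definition 3) requires, inclusively: SBP ≤ 130
and DBP ≤ 85 mmHg with no antihypertensive medication; fasting glucose
≤ 100 mg/dl; HOMA-IR ≤ 5.1; TG/HDL ≤ 1.65 (men) / 1.32 (women); and
hsCRP ≤ 0.3 mg/dl.  Missing fields raise errors rather than passing
silently — the classifier is meant for complete clinical records.
"No hypertension" is interpreted as *both* pressure bounds plus the
medication flag.

## Synthetic cohorts

The generator emulates the statistical structure the downstream
analysis assumes, not read-level sequencing.  Defaults are the study
conditions: 8 MHO vs 21 MAO subjects and 2,000 genes containing three
planted 50-gene modules.

* **Counts.**  Gene g in sample s is NB with mean
  `2^(b_g + λ_g f_m(s) + x_s Δ_g) · L_s / L̄` and dispersion φ_g, drawn
  as a gamma–Poisson mixture.  Baselines b_g ~ U(1, 9) log2 counts;
  library-size factors L_s are log-normal (σ = 0.25);
  φ_g ~ Gamma(2, 0.06), median ≈ 0.1 — a typical bulk RNA-seq scale,
  chosen because no empirical dispersions are available for the
  original cohort.
* **Modules.**  Each module m has a latent Gaussian factor f_m per
  sample and loadings λ_g ~ N(0.8, 0.15²) on its member genes
  (background genes have λ = 0).  This is the minimal correlated-block
  structure a co-expression network analysis assumes.  With these
  values the within-module correlation on the log2 scale is ≈ 0.6–0.75
  at typical expression levels.
* **Association.**  The designated module's factor is shifted down by
  `assoc_effect` (default 1.5 SD) in MHO samples, so the module is
  under-expressed in MHO and every member gene carries a true log2
  fold change of −assoc_effect·λ_g.  The factor noise is centred
  within each group before the shift is applied, so the *realized*
  standardized shift equals the configured one: with only 8 MHO
  subjects, the group mean of the raw noise has SD ≈ 0.35 and would
  otherwise randomize the planted effect by a large fraction.
* **Clinical covariates.**  Glucose, hsCRP, HOMA-IR and TG/HDL are
  log-normal per group, calibrated to the reference cohort's printed
  means and SDs (all four variables are positive and right-skewed, and
  the reference table reports geometric means, supporting the
  log-normal choice).  TG/HDL is coupled to the associated module's
  factor through a Gaussian copula (default r = 0.6) so the
  driver-ranking stage has recoverable truth.  HDL itself and blood
  pressures use plausible values the reference table does not specify
  (HDL ≈ 55 ± 12 / 48 ± 11 mg/dl; normotensive 118/74, hypertensive
  142/92 mmHg).  Sex, smoking, drinking and hypertension flags are
  Bernoulli with the reference group frequencies.  Subjects whose
  draws contradict their assigned group under definition 3 are redrawn
  (bounded retries), after which ≥ 95 % classify back correctly.
  Truncation makes some generated moments deviate slightly from the
  configured ones (e.g. MHO hsCRP mean 0.12 vs 0.13 configured).
* **What it does not emulate:** read-level error, gene length effects,
  batch structure, trended mean–dispersion relationships, or
  correlated clinical comorbidity beyond the TG/HDL coupling.  Passing
  tests therefore demonstrate correctness of the statistical
  machinery under the assumed generative model, not performance on
  real cohorts.

## Normalization and QC

Between-sample normalization is the weighted trimmed mean of M-values:
per-gene log2 ratios against a reference sample (the one whose
upper-quartile CPM is closest to the cohort mean) are doubly trimmed —
30 % on M, 5 % on A — and averaged with inverse asymptotic-variance
weights; factors are rescaled to geometric mean 1.  These are the
published defaults of the method; the implementation reproduces the
reference R implementation to ~1e-10 on a frozen toy matrix.  Because
the precision weights depend on depth, invariance to a pure depth
rescaling is approximate (relative changes ~1e-4).

Genes below 1 CPM (raw-library CPM, pre-normalization) in fewer than 3
samples are removed before any analysis; filtering precedes
normalization and network construction.  Log2-CPM uses a prior count
of 0.5.  Sample outliers are flagged by PCA on log-CPM: scores on the
top 2 components are robustly standardized (median/MAD) and a sample
is flagged when the norm of its z-scores exceeds 3·√2 — three robust
SDs per component.  The per-component calibration matters: a plain
norm threshold of 3 flags ~1 % of legitimate samples in 2-D, while
genuine outliers (e.g. a sample with permuted gene values) sit at
norms of 100+.

## Network construction and modules

Gene–gene similarity is the Pearson correlation of log2-CPM profiles.
The unsigned weighted adjacency is `a_ij = |s_ij|^β`; the soft power β
is the smallest candidate in 1…20 whose degree distribution is
approximately scale-free — R² ≥ 0.8 of the regression of
log10(binned degree frequency) on log10(mean degree) over 10
equal-width bins, with the fit forced to 0 when the slope is
non-negative.  Unsigned adjacency is used because gene significance is
defined through absolute correlation.  Two caveats we verified and
document rather than hide: pure-noise networks also satisfy the
criterion at high powers (fit ≈ 0.9 at β ≥ 9), and below ~1,000 genes
the selection is volatile (β = 2 can pass by chance and is then too
soft to separate modules).  At the default 2,000-gene scale the rule
behaves well (β = 3–7, fit 0.80–0.90 across seeds).

Clustering uses the topological overlap measure

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

average-linkage (UPGMA) hierarchical clustering on 1 − TOM, and a
static cut.  The cut height default is **0.95**: at 0.99 the static
cut either absorbs dozens of background genes per module and produces
many spurious ≥10-gene noise branches, or (on some seeds) collapses
the entire network into a single module, because the average
dissimilarity of background genes to a large cohesive branch falls
just below 0.99.  At 0.95 planted modules are recovered cleanly
(recall ≥ 0.84, Rand ≥ 0.97 across seeds tried) and background stays
unassigned.  Branches below 10 genes are unassigned (label 0); labels
are contiguous and ordered by size.  Modules whose eigengenes
correlate above 0.75 are merged iteratively, recomputing eigengenes
after each merge.  A definitional nuance: the TOM of two *identical*
genes is below 1 (the shared-neighbour term squares the adjacencies),
so duplicates merge first but not at height zero.

## Module–trait association

A module eigengene is the first principal component of the
gene-standardized module submatrix across samples, unit variance, sign
aligned with the module's mean standardized expression.  Module
membership MM = |cor(gene, eigengene)| and gene significance
GS = |cor(gene, trait)| (point-biserial for the binary MHO trait; the
signed MM is also available).  Module–trait association is the partial
Pearson correlation of each eigengene with the trait, controlling for
sex by residualizing both sides on an intercept + covariates; p-values
use the t-distribution with n − 2 − #covariates df, BH-adjusted across
modules.  A module is significant only under the dual rule: FDR
q ≤ 0.05 AND the MM–GS correlation over its member genes is positive
with p ≤ 0.05 (hub genes of a plausible trait module should be the
most trait-correlated ones).  Gene-set over-representation is the
one-sided hypergeometric tail, equivalent to a one-sided Fisher exact
test, BH-adjusted across sets.

Under the default planted effect (d = 1.5, 8 vs 21) the eigengene–
trait correlation is ≈ −0.5, which clears the dual rule when the
module count is in the single digits; with no planted effect the rule
fires in well under 5 % of seeds.

## Differential expression

Per-gene NB GLMs with log link and offsets equal to log effective
(TMM-scaled) library sizes are fitted by IRLS, vectorized across
genes.  Dispersion estimation is a two-level scheme: the common
dispersion maximizes the mean Cox-Reid adjusted profile likelihood
(APL) over a log-spaced grid (1e-6…10, 36 points, parabolic
refinement), and tagwise dispersions maximize each gene's APL plus
`prior_df / residual_df` times the shared mean APL (weighted-likelihood
shrinkage, prior_df = 10).  This deliberately omits the trended
mean–dispersion pipeline of the reference package.  The group effect
is tested by a likelihood-ratio test (χ², 1 df) of nested GLMs with BH
FDR; genes with |log2FC| > 0 and q ≤ 0.05 are flagged.  The fit
matches the statsmodels NB GLM to ~1e-6 at fixed dispersion, the null
type-I error is 0.05 at nominal 0.05, and a known dispersion of 0.2 is
recovered within ±0.01.

A deviance goodness-of-fit screen flags genes with upper-tail χ²
p ≤ 0.01 (the flag threshold is our choice; the screen is a pointer
for manual inspection, and the deviance χ² approximation is
conservative at n = 16).  Two offsets subtleties are load-bearing:
testing a module-gene subset must keep the *full-matrix* normalization
(co-regulated genes' own column sums track the group effect and would
absorb it), and one-sided planted fold changes induce composition bias
that TMM largely removes.  By default the pipeline tests only the
genes of trait-associated modules; multiple-testing is then over that
restricted set, which changes q-values — an `--all-genes`/
`de_all_genes` override exists.

Power is estimated by simulation: NB counts per (|log2FC|, mean) cell
plus null genes, run through the full dispersion-estimation + LRT
path, scoring the fraction of truly-DE genes at q ≤ FDR (default
0.15).  qPCR validation arithmetic uses the ddCt method with the
arithmetic mean of the reference-gene Cts and amplification efficiency
fixed at 2.

Under the generator's defaults the shared module factor contributes
within-group biological variance (effective extra dispersion ≈ 0.3 on
the natural-log scale), so per-gene power on module genes is ~0.6–0.7
— deliberately realistic, and the pipeline tests assert accordingly.

## Balanced random forests

Class imbalance (8 vs 21) is handled by a balanced bootstrap: every
tree draws the minority-class count from each class with replacement,
so per-tree OOB errors weight both classes equally.  Candidate
features per split are `mtry = floor(p/2)` — deliberately not √p — and
forests default to 10,000 trees (tests and the pipeline scale ntree
down, which we verified leaves OOB statistics stable to ±0.02 AUC).
OOB votes accumulate only from trees for which a sample was out of
bag; AUC is the rank statistic of OOB vote fractions (ties half),
sensitivity/specificity threshold votes at 0.5 (ties to the reference
class).  Everything is bit-reproducible under a fixed seed.

Permutation importance: per tree, each feature is permuted within the
tree's OOB set (total permutation draws ≥ nPerm spread across trees)
and VIM_k is the mean per-tree increase in OOB error; constant
features get 0 by definition.  Note that within one finite dataset a
"noise" feature chance-correlated with the outcome has genuinely
positive expected VIM — the null distribution of noise VIMs is centred
at zero only across datasets.

Variable selection follows a three-step heuristic: (1) rank features
by mean VIM over independently seeded replicate forests; (2) keep
features above a data-derived noise threshold (mean + 2 SD of the
negative-VIM magnitudes, or the minimum positive mean VIM if none are
negative); (3) walk nested forests over the ranked set and keep the
smallest prefix whose OOB AUC is within one standard error of the
best.  In simulations the VIM *ranking* reliably puts planted
informative features on top; the prefix cut is the fragile part — on a
flat AUC plateau chance-correlated noise features can add ~0.002 AUC
and be retained, and redundant informative features can saturate the
AUC early.  This is an inherent small-n limitation, stated rather than
patched with an arbitrary parsimony constant.

Driver ranking regresses each module gene's expression on the four
metabolic parameters (hsCRP, TG/HDL, glucose, HOMA-IR) with bootstrap
forest regressions (variance-reduction splits, same mtry rule),
tabulating the top-VIM parameter per gene, and classifies MHO from
each parameter alone and all four jointly, reporting OOB AUC per
model.  Constant or duplicated parameters are excluded with a warning.

## Pipeline

`run_full_analysis` chains simulate/load → phenotype → filter/TMM/QC
(outlying samples are dropped and normalization recomputed) → network
→ module–trait association → DE on associated-module genes → per-module
balanced RF with VIM, optional variable selection, and driver ranking
on the first associated module.  Stage outputs are pure functions of
(inputs, config, seed); re-running a config reproduces the report
byte-for-byte.  Stage failures abort with the stage name (CLI exit
code 3; config errors exit 2).

## Problem sizes used in tests

Unit fixtures use a 1,000-gene cohort (three 40-gene modules); the
end-to-end checks use the full default cohort (2,000 genes, seed 1);
null calibration runs 20 reduced cohorts (500 genes, two 30-gene
modules); DE calibration uses 2,000-gene null and 2,000-gene planted
simulations at 8 vs 8; selection recovery uses 55-vs-95 cohorts with 5
informative and 50 noise features.  Forest tests use 200–2,000 trees.
These sizes were chosen so every property is measurable with
comfortable statistical margin at desk scale.

## Known limitations

* Static-cut module detection (no dynamic branch pruning); the cut
  height is a config knob.
* The dispersion model is two-level (common + tagwise), not trended.
* MM is reported as |r| to keep it in [0, 1]; the signed value is
  available but the dual rule uses the absolute convention.
* The scale-free criterion is necessary, not sufficient: noise
  networks can pass at high powers, and the power selection is
  unstable below ~1,000 genes.
* Variable selection inherits the small-n ambiguity of
  chance-correlated predictors discussed above.
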