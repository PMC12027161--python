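# Methods

`loadrisk` implements a case/control risk-prediction pipeline for
late-onset Alzheimer's disease (LOAD) built around three ingredients: a
control-standardized polygenic score, an ordinal APOE diplotype code,
and a k-nearest-neighbors (KNN) classifier tuned for sensitivity. This
note describes the models and procedures, the choices made where the
design was genuinely open, and what the bundled synthetic cohorts do and
do not demonstrate.

## The genetic score

For individual *j* with effect-allele dosages *d<sub>ij</sub>* ∈
{0, 1, 2} over SNPs *i* with GWAS effect sizes *β<sub>i</sub>*, the raw
score is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>j</sub> = Σ<sub>i</sub> (g<sub>ij</sub> + 1) · b<sub>i</sub>

where (g, b) is the *risk-oriented* encoding: for β<sub>i</sub> ≥ 0,
g = d and b = β; for β<sub>i</sub> < 0 the dosage is flipped
(g = 2 − d) and b = |β|, so the "risk homozygote" is always the
β-increasing homozygote and g + 1 codes protective homozygote /
heterozygote / risk homozygote as 1 / 2 / 3 (no zeros in the input
matrix). The reported score is standardized against controls:

&nbsp;&nbsp;&nbsp;&nbsp;z<sub>j</sub> = (S<sub>j</sub> − μ<sub>control</sub>) / σ<sub>control</sub>,

with μ, σ (n−1 denominator) computed over the control group — by
default the *training* controls, the leakage-safe reading of
"standardize against controls" (switchable). Because standardization is
affine-invariant, the "+1" offset and the orientation convention change
no z-score; the test suite asserts this to 1e−12 for offsets
c ∈ {0, 1, 5}.

Missing dosages that survive QC (≤ 10% per SNP) are imputed before
summation with the training-control mean oriented dosage of that SNP
(alternatives: overall mean, zero).

## APOE diplotypes

Haplotypes at (rs429358, rs7412), both given as C-allele counts:
ε2 = (T, T), ε3 = (T, C), ε4 = (C, C). Ordinal risk codes:
{ε2/ε2, ε2/ε3} → −1, ε3/ε3 → 0, {ε2/ε4, ε3/ε4} → 1, ε4/ε4 → 2. The
unphased double heterozygote (1, 1) is resolved to ε2/ε4, the standard
convention given the rarity of ε1. Genotypes with more C alleles at
rs429358 than at rs7412 force an ε1 = (C, T) haplotype; to keep the
mapping total over all nine genotype combinations, ε1 is coded as
ε4-equivalent risk (it carries the rs429358 risk allele). These
resolutions are logged per individual.

## Quality control

Four exclusion rules, applied in one pass: SNPs with zero variance over
observed genotypes (an all-missing SNP counts as zero-variance), SNPs
with missing rate **strictly** greater than 10%, SNPs with MAF
**strictly** below 0.01 (MAF over observed genotypes only), then —
computed on the SNP-filtered matrix — individuals missing strictly more
than 10% of the retained SNPs. Boundary values survive. SNP statistics
are not recomputed after individual removal; iterating the two passes
to a fixed point is available as `iterate=True` but off by default.
When several rules match one SNP, the reported reason follows the
precedence zero-variance → missingness → MAF (reporting only; the
removal set is unaffected).

## Classifier

KNN from scratch: the case probability of a query is the case fraction
among its k nearest training rows under Euclidean, Manhattan or cosine
(1 − similarity) distance. Distance ties are broken by training-row
order via a stable sort; on continuous features ties have probability
zero and results are permutation-invariant (tested). Classification is
`probability ≥ threshold` — boundary inclusive, which maximizes
sensitivity at any printed cut-off.

k is chosen by stratified 5-fold cross-validation over 60 candidate
values; the grid is the odd integers 1–119 (odd k avoids 50/50 votes at
the 0.5 threshold), the selection criterion is mean validation accuracy
at threshold 0.5 (switchable to AUC), and ties go to the smallest k.
Class imbalance is addressed on the **training partition only**: random
oversampling of the minority class (duplication with replacement to
exact parity, all original rows retained) or subsampling of the
majority class (without replacement to the minority count). The test
partition keeps the natural prevalence. The 70/30 split is stratified
by label (switchable).

## Evaluation

Sensitivity, specificity, accuracy, precision and F1 from the confusion
matrix, with 0/0 ratios reported as NaN plus a warning. The ROC curve
sweeps every distinct predicted probability as a threshold under the
same ≥ rule, and the AUC is the trapezoid area. KNN probabilities are
multiples of 1/k, so tied probabilities are common; the trapezoid over
a tied block awards half credit, making the AUC exactly the
tie-corrected concordance statistic (asserted to 1e−10 against a
brute-force pairwise oracle). The threshold sweep uses a 0.01-resolution
grid by default; threshold selection supports Youden's J and a
constrained policy (maximal sensitivity subject to a specificity
floor, e.g. 0.61, returning the smallest feasible threshold).

## Inferential battery

Numeric predictors (z-score, age, cholesterol): Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
and Hedges' g = J·(mean<sub>case</sub> − mean<sub>control</sub>)/s<sub>pooled</sub>
with J = 1 − 3/(4(n₁+n₂) − 9) — positive when cases are higher.
Categorical predictors (sex, smoking, diabetes, APOE code): Pearson
chi-square without continuity correction (flag available) and Cramér's
V = √(χ²/(n·(min(r,c)−1))). The per-APOE-group analysis tests each
group's case/control split against the cohort-wide proportions with a
df-1 goodness-of-fit test; a two-proportion variant would be an easy
extension but the goodness-of-fit form matches the group-vs-cohort
comparisons the battery is meant to support. No multiple-testing
adjustment is applied by default (raw p-values are reported).

## Synthetic cohorts

The generator draws a source population — Hardy–Weinberg genotypes at
per-SNP MAFs uniform on (0.01, 0.5), β ~ N(0, 0.05²), APOE haplotypes
from European-like allele frequencies (ε2 0.08, ε3 0.78, ε4 0.14) under
random mating, ages uniform on [60, 99], cholesterol ~ N(5.7, 1.1)
mmol/L, sex/smoking/diabetes Bernoulli — and assigns case status by a
liability threshold:

&nbsp;&nbsp;&nbsp;&nbsp;L = w<sub>score</sub>·Z + w<sub>apoe</sub>·APOE + w<sub>age</sub>·age′ + w<sub>diab</sub>·diabetes + w<sub>chol</sub>·chol′ + ε,&nbsp;&nbsp;ε ~ N(0, 1),

labeling individuals above the (1 − prevalence) quantile (default
prevalence 0.23) as cases and drawing until the requested counts are
reached (defaults 2547 cases / 8699 controls). Default weights
(0.62, 0.95, 0.50, 0.60, −0.10) were fixed once by a coarse grid search
so the default cohort reproduces the intended effect structure — large
score and age differences (g ≈ 0.75 and ≈ 0.65), a strong APOE gradient
(V ≈ 0.34), a modest diabetes association, a small negative cholesterol
difference, and null sex/smoking. Genotype missingness is injected MCAR
at 5% by default (1–10% is realistic for array data).

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, relatedness, informative missingness,
age-dependent covariate drift, or any real genotype-phenotype coupling
beyond the linear liability. Passing tests therefore demonstrate that
the pipeline's machinery is correct and well calibrated under its own
model assumptions, not that the classifier would attain any particular
performance on real biobank data.

`plant_qc_violations` overwrites randomly chosen columns/rows with
known violations of each QC rule (constant columns; single-heterozygote
columns below MAF 0.01, which needs > 50 individuals; columns and rows
at 20% missingness confined so the violations stay independent) and
records the victim ids, enabling exact round-trip tests of the filter.

## Numerical and reproducibility choices

* Every stochastic operation is a pure function of its inputs and a
  seed. The pipeline derives per-stage sub-seeds by stable hashing of
  the stage name with the master seed, so changing one stage's strategy
  never perturbs another stage's draw (e.g. the split is identical
  across sampling strategies).
* Euclidean distances use the Gram-matrix identity with clipping at
  zero; Manhattan distances are computed in row blocks capped at ~2²⁵
  temporary elements; cosine distance raises on zero-norm vectors.
* Degenerate inputs raise typed errors (`DegenerateDataError`,
  `StratificationError`, ...) rather than returning NaNs, except for
  the documented NaN metrics on empty confusion cells.
* Scaled problem sizes: the repository's own acceptance checks simulate
  cohorts of 1000–2500 individuals at the default 23:77 imbalance and
  379 SNPs — large enough for stable effect-size ordering and
  calibrated null AUC (mean over 20 seeds within [0.47, 0.53]), small
  enough for quick iteration.

## Known limitations

* Brute-force KNN is O(n·m·d) per prediction batch; fine for cohorts of
  ~10⁴, not for biobank-scale inference (no KD-tree/ball-tree).
* Cosine distance on column-standardized features is fragile (a query
  near the feature mean has a near-zero norm); it is included as a
  configurable metric, and its weak performance on standardized inputs
  is expected, not a defect.
* The per-SNP feature set dilutes a weak polygenic signal across
  hundreds of scaled columns, so SNP-only KNN models hover near chance
  at n ≈ 10³; the aggregated z-score recovers the signal. This mirrors
  the qualitative ordering the pipeline is designed to expose
  (combined ≥ SNP-only), not any particular published operating point.
* The liability model is linear with Gaussian noise; no interactions,
  no non-linear age effects, no measurement error in covariates.
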