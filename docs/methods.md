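# Methods

This note documents the statistical procedures implemented in `lipidcad`,
the assumptions behind them, the synthetic cohorts used to validate them,
and the design choices made where a published description left the design
open.

## The analysis problem

The package targets studies that relate a plasma lipidome (hundreds of
species quantified by LC-MS/MS, log-transformed) to subclinical coronary
artery disease (sCAD) defined from CT-derived coronary artery calcium
(CAC). Participants on statins are excluded (lipid-lowering therapy
perturbs the measurement of interest). The remaining participants are
labeled sCAD− when CAC = 0 and sCAD+ when CAC is at or above the 50th
percentile for their sex and age decade; participants with positive but
below-median CAC are set aside as intermediate. Because the percentile is
computed within sex × age strata, age and sex are largely neutralized as
label predictors — the residual signal a risk score can exploit comes from
the modifiable risk factors and from the lipidome.

The percentile reference is the within-cohort empirical distribution of
positive CAC among non-statin participants of each stratum (decade bins,
the convention of CAC reference tables). Strata with fewer than two
positive-CAC members fall back to a sex-only stratum with a warning. An
external population CAC chart is deliberately out of scope; the internal
reference keeps the package self-contained.

The analytical cohort is split into discovery and validation by
recruitment order (first ⌈fraction·n⌉ recruited → discovery; default
fraction 394/580). All model fitting — normalization factors, feature
selection, risk-score coefficients, classifiability — uses discovery data
only; validation enters only through frozen transforms and predictions.

## RUV-III with pseudo-replicates

Batch effects are removed with RUV-III, which estimates hidden factors
from replicate samples and negative-control features. True replicates are
unavailable in a cohort study, so study samples are grouped into 80
clinically homogeneous pseudo-replicates by Ward agglomerative clustering
on standardized age and BMI plus 0/1 sex, hypertension, smoking, diabetes,
and hypercholesterolemia flags. Each QC sample type (pooled QC, technical
QC, blank, NIST 1950 reference plasma) forms one additional replicate
group, giving 84 groups in the default layout. Ward linkage was chosen for
its balanced clusters; the weighting of mixed-type covariates (binaries as
0/1 against standardized continuous variables) is a pragmatic default.

With column-centered data `Y` (n × p), membership matrix `M` (n × m),
control set `c`, and `k` factors (default 8):

1. `Y0 = (I − M(MᵀM)⁻¹Mᵀ) Y` — within-replicate residual;
2. `U` = top-k left singular vectors of `Y0`;
3. `alpha = Uᵀ Y` (k × p);
4. `W = Y_c alpha_cᵀ (alpha_c alpha_cᵀ)⁻¹` (n × k), estimated from the
   control features only;
5. adjusted data = `Y − W alpha` + column means.

Validation transfer re-centers the new matrix on its own column means,
re-estimates `W` from the new cohort's control features with the frozen
`alpha`, and subtracts. Which means are added back is controlled by a
flag: `restore="own"` (the default) restores the new cohort's means, so
validation column means are preserved exactly; `restore="model"` restores
the discovery means stored in the model. The distinction matters when
batches align with the recruitment order: the validation cohort's own
column means then contain the validation batches' offsets, and restoring
them leaves a per-species level shift between the adjusted discovery and
validation matrices. Rank-based quantities (AUC) are unaffected, but a
discovery-trained risk model's absolute probabilities — and with them the
binary calls — miscalibrate badly. The pipeline therefore transfers with
`restore="model"` before prediction. Applying the transfer to the
discovery matrix itself reproduces the fit output to numerical precision
under either setting (discovery means and own means coincide there), which
is tested.

Negative controls are species significantly associated with batch (one-way
ANOVA across batches, Benjamini-Hochberg FDR < 0.05) but not with age
(correlation t test, raw p > 0.05) or sex (two-sample t test, raw
p > 0.05). When class labels for the fitting cohort are supplied, species
associated with the class (t test, p > 0.05 required) are additionally
excluded. This extra screen matters because negative controls must carry no
wanted variation: if strongly disease-associated species enter the control
set, step 4 regenerates the disease direction in `W` and step 5 subtracts
it. With realistic (small) effect sizes the screen changes little; with
the large planted effects used in stress tests it is the difference
between preserving and destroying the signal. The pipeline passes
discovery labels; validation labels are never consulted.

PCA diagnostics report, per principal component of the column-centered
matrix, the variance explained and the R² from regressing the PC score on
batch (dummy-coded), age, and sex. On synthetic cohorts with planted batch
offsets (SD 0.5 on the log scale), the maximum R² against batch among the
first 30 PCs drops from ≈1 to below 0.01 after adjustment; the acceptance
script recomputes exactly this quantity.

## Per-species association testing

Each species is tested by maximum-likelihood logistic regression of class
on log concentration (statsmodels Newton iterations — equivalent to IRLS —
tolerance 1e-8, max 100 iterations), unadjusted and adjusted for BMI,
hypertension, current smoking, diabetes, and hypercholesterolemia. Age and
sex are not in the default adjustment set (they are already absorbed by
the percentile labeling) but can be added by extending the covariate
frame. Effects are odds ratios per unit log-concentration with 95% Wald
intervals — the standard for forest plots; profile-likelihood intervals
are not offered. Perfectly separated or non-convergent species are
flagged, get no p-value, and are excluded from the BH adjustment, which is
applied within each model variant. The forest export keeps species whose
adjusted-model BH-adjusted p falls below the FDR threshold, sorted by it,
with significance stars at 0.05 / 0.01 / 0.001.

Associations are fitted on the combined (discovery + validation) adjusted
data by the pipeline — association testing is descriptive, not part of
model training.

## Risk models

**FRS.** The Framingham 10-year general cardiovascular risk is computed
from the published sex-specific equation: risk = 1 − S₀(10)^exp(Σβx − μ),
with coefficients on log age, log total and HDL cholesterol (converted
from mmol/L to mg/dL internally), log SBP (treated/untreated — read from a
`bp_treated` column when present, otherwise from the hypertension flag),
smoking, and diabetes. Two reference profiles computed by an independent
hand implementation are frozen as regression fixtures. Ages outside 30–74
are clamped with a warning. The FRS *model* is a one-covariate unpenalized
logistic regression of class on FRS (its ROC is therefore a monotone
transform of FRS itself).

**LRS.** The lipid risk score is an L2-penalized logistic regression
maximizing ℓ(β) − λ‖β₋₀‖²/2 (intercept unpenalized; features standardized
on training data; lbfgs, gradient tolerance 1e-6). "Ridge" fixes the
penalty type; λ is tuned on a log grid 10⁻³…10³ by default. Feature
informativity is the mean absolute standardized ridge coefficient across
bootstrap resamples (an explicit design choice — the quantity is not
uniquely defined in the literature; a univariate-AUC ranking can be
substituted by ranking externally and passing the feature list). Per
bootstrap resample, every (penalty, n_features) grid point is scored by
out-of-bag AUC using the resample's own ranking; the grid point with the
highest mean out-of-bag AUC wins, and the final model uses the top
`n_features` (default 200) species of the aggregate ranking. The ranking
fit is regularized at the median grid penalty: an under-penalized ranking
fit at p ≈ 683 with a few hundred in-bag samples is dominated by noise
coefficients and misses genuinely informative species.

**Combined model.** Ridge over the selected species plus FRS as one
additional predictor, same penalty.

Binary calls use the Youden-optimal threshold (maximizing sensitivity +
specificity − 1) placed on training risk scores; a fixed 0.5 threshold is
available. For wide problems (≥10 features) the threshold is placed on
out-of-fold predictions from a deterministic 5-fold split of the training
data rather than on in-sample probabilities — a 200-feature ridge fit
separates its own training data nearly perfectly, and a cutoff placed in
that optimistic score distribution misses held-out cases. The threshold
remains a discovery-only quantity either way. Feature selection accepts an
optional discovery-id guard that raises if any non-discovery sample
reaches it.

## Individual classifiability and sub-cohort discovery

The individual classifiability score (ICS) of a discovery sample is the
fraction of repeats of stratified 5-fold cross-validation (default 50
repeats) in which the sample is predicted correctly by a ridge-logistic
model on the selected species. Scores are therefore multiples of 1/r. Rows
are canonically ordered by sample id before fold assignment, making the
scores invariant to input row order; each repeat is seeded as
seed + 131·repeat. Within-fold thresholds default to the training-fold
Youden cutoff — with imbalanced classes a fixed 0.5 cutoff degenerates to
majority calling, which saturates the minority class at ICS ≈ 0 and hides
any structure.

Candidate modifying variables (default BMI, hypertension,
hypercholesterolemia) are scanned by one linear regression each:
ICS ~ candidate + age + sex; the candidate with the smallest p-value on
its own coefficient wins. The cohort is then stratified at BMI 25 kg/m²
(boundary to the high group), applied independently to discovery and
validation.

Caveat: with a few hundred discovery samples and several hundred candidate
species, the selected feature set partially reflects chance correlations,
and the ICS — computed on the same discovery cohort — inherits a
stratum-neutral optimism from them. In stress tests the modifier scan
becomes reliable (BMI detected in ≥95% of seeds) at around a thousand
study samples; below that, seed-to-seed variability in the selection can
drown the stratum contrast even when the planted effect is large.

## Evaluation

AUC is the tie-aware Mann-Whitney concordance, (#concordant + ½#tied) /
(n₊n₋), computed via midranks and verified exactly against an O(n²)
pair-counting oracle. ROC curves enumerate all unique score thresholds.
DeLong's paired test estimates Var(AUC₁ − AUC₂) from the empirical
covariance of per-sample placement values (midrank form for ties) and
refers z to the standard normal; zero variance with equal AUCs returns
z = 0, p = 1 by convention. Sub-cohort evaluation computes predictions
once on the full validation set and partitions them by stratum; strata
with a single class are flagged rather than scored. The model-overlap
table cross-tabulates, among true sCAD+ validation samples, which of the
two risk scores called them correctly (both / LRS only / FRS only /
neither), with percentages against the sCAD+ denominator. Because the
overlap depends on the binary threshold, it is reported for the
Youden-threshold calls by default and recomputes directly from any other
call vectors.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
mass spectra. Study conditions are its defaults:

| parameter | default | meaning |
|---|---|---|
| n_study | 600 | study samples before exclusions |
| n_species | 683 | lipid species |
| n_batches / batch_sd | 3 / 0.5 | contiguous-recruitment-block batches; log-scale offset SD |
| n_informative | 30 | species carrying class effects |
| effect_low/high_bmi | 0.5 / 0.5 | per-residual-SD log-odds in each BMI stratum |
| noise_sd | 0.3 | residual log-scale SD |
| qc_noise_sd | 0.05 | technical replicate SD |
| statin_prob | 0.33 | statin-user fraction |
| age/sex loading SD | 0.012 / 0.03 | per-species covariate loadings (on ~25% of species) |
| cac_zero_intercept | 0.4 | zero-inflation level (≈ half the cohort at CAC 0) |
| cac_covariate_weight | 1.0 | strength of the risk-factor → CAC channel |

Clinical covariates match a typical CTCA-referral cohort (age 61 ± 12 y,
45% female, BMI 26.9 ± 4.8, 39% hypertension, 8.7% diabetes, 59%
hypercholesterolemia, 6.4% current smoking). CAC is zero-inflated
log-normal: the point mass shrinks with age and male sex; both parts gain
a risk-factor contribution scaled by `cac_covariate_weight` — because the
labels are percentile-adjusted for age and sex, this knob effectively sets
how informative a Framingham-type score is about the labels. Lipid
log-concentrations are species baseline (Normal(log 10, 1) a.u.; units are
unidentifiable, so the scale is arbitrary but fixed) + batch offset +
age/sex loadings + class effect + noise. The class effect is a two-level
switch at BMI 25 (no continuous interaction — matching what the pipeline
must detect). QC rows carry their batch's offset and technical noise only:
pooled QC at the pooled study-signal mean, technical QC replicating one
reference aliquot, blanks at baseline − 5 log units, NIST 1950 at baseline
plus a fixed reference offset.

The age/sex loadings are deliberately small: loadings aggregate across
species into a multivariate "lipidomic age" axis, and because sCAD−
participants (zero CAC) are systematically younger, that axis predicts the
class. At the default loadings the aggregated channel reaches AUC ≈ 0.6,
consistent with the modest lipidome-only AUCs reported for this problem;
stronger loadings let a classifier reach AUC ≈ 0.9 from age alone, which
no published lipidome-only model approaches.

What the generator does not emulate: correlation blocks among lipid
species (species are conditionally independent given the factors), heavy
tails and missingness, drift within batches, nonlinear covariate effects.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under the stated generative model, not performance on real
plasma lipidomes.

## Numerical choices and degenerate inputs

- Logistic fits: lbfgs (ridge) / Newton (per-species), tolerances 1e-6 /
  1e-8; non-convergence raises (ridge) or flags the record (per-species).
- `alpha_c alpha_cᵀ` condition number above 1e12 raises with advice to
  reduce k; k must not exceed n − m (the replicate residual rank).
- Ties: midranks everywhere (AUC, DeLong placement values); Youden
  thresholds evaluate at tie-block boundaries.
- Empty control set, single-class folds (after 10 re-draws), and
  out-of-range configuration values raise typed errors that the CLI maps
  to exit codes 2 (configuration) and 3 (data).
- All randomness flows from one master seed through named per-stage
  `SeedSequence` streams; derived seeds stay below 2³¹.

## Test and acceptance problem sizes

The test suite exercises the default 683-species geometry where the
property depends on it (batch-removal bound, near-identity adjustment,
clean-cohort transfer) and smaller matrices (80–300 species, 200–600
samples) elsewhere. The direction check for the BMI-modified signal uses
n_study = 1000 with effect 2.5 SD⁻¹ in the low-BMI stratum, no effect in
the high stratum, and `cac_covariate_weight` 0 over 20 seeds; the null
calibration uses balanced all-null cohorts (no informative species, no
batch effects, no covariate loadings, `cac_zero_intercept` −0.3) so that
mean classifiability has expectation exactly ½. The acceptance script
(`scripts/acceptance.py`) regenerates the planted-batch cohort at the
default size and reports the post-normalization maximum batch R².

## Known limitations

- The ICS-based modifier scan needs roughly 1000 study samples to be
  reliable under the stated conditions; the package reports the scan table
  rather than only the winner so marginal calls are visible.
- The combined (lipids + FRS) model penalizes the FRS coefficient along
  with the species coefficients; with 200 noisy features it can sit
  slightly below the pure FRS model out of sample.
- Percentile labeling uses the internal cohort as reference; cohorts
  enriched for high CAC will shift the sCAD+ boundary accordingly.
- RUV-III with pseudo-replicates removes any variation shared within the
  top-k residual factors, including disease signal if the control screen
  misses it; the class-label screen mitigates but cannot eliminate this
  when effects are weak and diffuse.
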