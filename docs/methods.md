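# Methods

## Problem and model

The package analyses gene-by-smoking interaction on the FEV₁/FVC ratio
(×100) in subjects with normal lung function (ratio ≥ 70). Pulmonary
function is noisier in smokers than non-smokers, so ordinary least squares
is miscalibrated; the engine instead uses two-stage feasible weighted
least squares.

**Stage 1 (weights).** The covariate-only model (intercept, age, sex,
BMI, age×sex, pack-years, optional PCs) is fitted by OLS separately
within the non-smoker and smoker strata; columns constant within a
stratum (pack-years among never-smokers) are dropped. The unbiased
residual variance σ̂²_j = RSS_j/(n_j − p_j) of each stratum defines the
per-subject weight w_i = 1/σ̂²_stratum(i). Weights are SNP-independent and
estimated once per scan; stage 2 treats them as known (no
degrees-of-freedom correction), the usual feasible-WLS convention.

**Stage 2 (per-SNP fit and test).** For each variant, the full model adds
SNP and SNP×pack-years terms and is fitted by WLS:
β̂ = (XᵀWX)⁻¹XᵀWy, SEs from σ̂²·diag((XᵀWX)⁻¹) with σ̂² = WRSS/(n−p), Wald
p-values from the t distribution with n−p df. The 2-df joint null
H₀: β_SNP = β_INT = 0 is tested by likelihood ratio,
LR = n·log(WRSS₀/WRSS₁) against χ²₂ — algebraically identical to twice the
profiled Gaussian log-likelihood difference when both fits share weights —
or by F = ((WRSS₀−WRSS₁)/2)/(WRSS₁/(n−p_full)) against F(2, n−p_full).
Both are always computed; the LR p-value is the default headline, with a
flavor switch, since the two agree closely at cohort sizes (tested to 10%
relative on the −log₁₀ scale at n ≥ 1,000).

The genome scan uses per-SNP complete cases; the null fit is cached per
missingness pattern, and within a pattern the SNP block is solved by
residualizing the (weighted) SNP and interaction columns against the
covariates, so a 20,000-SNP scan at n = 2,000 runs in seconds. Variants
whose SNP/interaction block is numerically rank-deficient (monomorphic
variants, or strata where all pack-years are zero) are flagged
non-estimable rather than erroring.

**Model comparison.** The profiled log-likelihood is
−n/2·(log 2π + log(WRSS/n) + 1) + ½Σlog wᵢ, and AIC counts every
regression coefficient plus one variance parameter. `aic_compare` reports
AIC(unweighted) − AIC(weighted) on the same rows; positive differences
prefer the weighted fit. Because stage-1 weights are treated as known, the
parameter counts of the two fits are equal.

**Diagnostics.** Genomic inflation λ converts p-values to 1-df chi-square
quantiles and divides the median by 0.4549 (the χ²₁ median); the 1-df
convention is used regardless of the test's df, as is conventional for
quick calibration reads. QQ/Manhattan exports are plain tables (expected
quantiles (i−0.5)/m; cumulative genome coordinates; 5×10⁻⁸ reference
line).

## Synthetic cohort generator

The generator emulates a middle-aged East-Asian population cohort with
spirometry so that every downstream stage is testable without
controlled-access data. Defaults (one calibration, not revisited):

| parameter | default | basis |
|---|---|---|
| n | 7,473 | discovery cohort size |
| never/former/current | 63.8 / 15.3 / 20.9 % | cohort descriptives |
| pack-years (ever-smokers) | mean 22.8, SD 17.2 | cohort descriptives |
| age | 52.0 ± 8.9 y | cohort descriptives |
| male fraction | 44.3 % | cohort descriptives |
| BMI | 24.7 ± 3.1 kg/m² | cohort descriptives |
| covariate effects | age −0.10, sex −0.60, BMI −0.08, age×sex 0, pack-years −0.045 points | literature-scale lung-function slopes |
| residual SD | non-smoker 5.0, smoker 5.8 | see below |
| marginal FEV₁/FVC | 81.4 ± 5.4 | implied; mean used for intercept calibration |

The stratum residual SDs are not published; 5.0/5.8 were chosen once so
that covariate-driven variance (≈1.4) plus the stratum mixture
(0.638·5.0² + 0.362·5.8² ≈ 28.1) reproduces the printed marginal SD of
5.4. Experiments that prescribe a stratum SD ratio (e.g. ratio 2 for null
calibration) set the sigmas explicitly.

**Pack-years.** Ever-smokers draw from a normal truncated at zero whose
*truncated* mean/SD equal the configured targets; the parent parameters
are solved by moment matching (naive truncation of N(22.8, 17.2²) would
have mean 25.9). A zero-truncated normal cannot exceed a coefficient of
variation of 1, so targets with SD ≥ mean (the health-checkup cohort
prints 16.2 ± 24.1) fall back to a moment-matched gamma. Whether the
published pack-years moments refer to ever-smokers or current smokers is
not stated; the generator treats them as ever-smoker moments.

**Phenotype.** y = intercept + covariate terms + β₆·g + β₇·g·PY + ε with
ε drawn per stratum. The generator emits rows with FEV₁/FVC < 70;
eligibility filtering is an explicit downstream step, matching the
cohort-construction order. `calibrate_intercept` solves, by a
deterministic root-find over per-sample truncated-normal means, for the
intercept under which the *eligible* subjects' expected mean equals the
target (truncation raises the retained mean by ≈0.25 points, so
calibrating the untruncated mean would miss).

**Genotypes.** Haplotypes are latent standard normals thresholded at
Φ⁻¹(MAF), so the MAF target is exact in expectation; within an LD block
the latents follow an AR(1) with lag-one correlation `ld_rho`, giving
tunable r² (validated against the bivariate-normal orthant probability).
Dosages are sums of two independent haplotypes. An optional second
subpopulation with shifted MAFs exists solely to give the PCA something
to find. `inject_missingness` and `soften_calls` (probability triplets
with a given certainty on the true class) create the inputs the QC layer
filters.

What the generator does **not** emulate: linkage maps and realistic
recombination, admixture beyond the two-subpopulation toggle, genotyping
batch effects, non-linear smoking effects, age-by-smoking survivor bias,
and measurement error in spirometry. Passing tests therefore demonstrate
the statistical machinery under the model's own assumptions, not
robustness to everything real cohorts contain.

## QC conventions

Filters are strict as printed: a variant fails when HWE p < 10⁻⁵,
MAF < 0.05, call rate < 95 %, or INFO < 0.5 (INFO only when probability
triplets exist); values exactly at a threshold pass. Samples fail when
missingness exceeds 5 % strictly. Sample QC runs before variant QC (the
order is configurable by calling them separately). The HWE test is the
plain conditional exact test ("as or more probable" configurations, no
mid-p), computed in log space with an e⁻⁹ tie tolerance and verified
against an exact integer-arithmetic enumeration oracle. The INFO score is
the IMPUTE-style ratio 1 − Σ(fᵢ−eᵢ²)/(2Nθ(1−θ)), clamped to [0,1], with
θ ∈ {0,1} returning 1 by convention. Regressions use expected dosages
when triplets are present, and per-SNP complete cases otherwise.

## Population structure

GRM = ZZᵀ/M over polymorphic variants with Z column-standardized at
mean 2f, SD √(2f(1−f)); missing dosages are mean-imputed (zero after
centering). This is the standard standardized estimator; no
allele-frequency weighting variant is applied, and PCs are computed on
post-QC variants without LD thinning by default. Eigenvectors carry a
deterministic sign (largest-magnitude loading positive). Note that
centering on in-sample frequencies makes off-diagonals average −1/(n−1),
not 0.

## Replication and follow-up

Cohort rules are explicit objects: the discovery-style rule keeps all
eligible subjects and pools former+current smokers as the weighting
stratum; the health-checkup rule excludes former smokers (their enrolment
correlates with cessation advice), restricts to age > 40, and weights by
never vs current. Replication of a term requires p < 0.05 *and* the
discovery sign when discovery directions are supplied (the direction
requirement is this package's own strictness); the 2-df overall effect is
additionally flagged at 0.1. Independence diagnostics are unadjusted by
default (a flag adds age and sex); perfect separation in the logistic
model is caught and flagged rather than raised. Predicted trajectories
evaluate the fitted linear predictor at a supplied covariate profile
(stratum-pooled means in the examples), so the pack-years slope for
genotype g is exactly β₅ + β₇·g.

## Numerical and experimental choices

- All randomness flows from `numpy.random.default_rng` seeds inside
  `SimulationConfig` or explicit seed arguments; identical configurations
  give bit-identical outputs.
- Rank deficiency is handled by minimum-norm least squares plus a flag,
  so degenerate designs (e.g. an all-zero SNP column) still yield the
  well-defined LR statistic 0.
- Pack-years are entered raw (zero for never-smokers), not centered,
  matching the model as written; centering would change the
  interpretation of β₆ (phenotype difference at zero pack-years).
- The null-calibration experiment runs n = 2,000 with 20,000 independent
  SNPs and stratum SD ratio 2. Note that λ from a single scan varies by a
  few percent across cohort realizations even with 20,000 SNPs — all the
  statistics share one phenotype vector and one weight estimate, so the
  scan-level median moves coherently with the realized residuals in the
  high-leverage (heavy-smoker) subspace; the reproduction script
  therefore averages λ over 10 independent null scans. The recovery
  experiments use 200 replicates at n = 7,473. Recovery replicates fit the *untruncated* cohort: selecting
  on the outcome (ratio ≥ 70) attenuates coefficients by construction, so
  the generating value is the estimand only pre-selection. For the same
  reason the eligibility filter shrinks the smoker stratum's post-filter
  residual variance below its generating value, which the calibration
  tests account for.
- Recovery experiments omit PCs: the generator plants no structure, so PC
  columns would be pure noise covariates.

## Known limitations

- No mixed-model association (PC adjustment only) and no robust/sandwich
  variance alternative to the weighted fit.
- The HWE test operates on best-guess genotype classes when calls are
  soft.
- Imputation itself (phasing, reference panels) is out of scope; the
  package only scores and filters already-imputed probabilities.
- The published cohort-scale results (specific SNP p-values, SNP counts
  surviving QC) require controlled-access genotype data and are not
  reproducible here; the synthetic experiments validate the machinery,
  calibration and effect-size recovery instead.
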