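# Methods

## Scope and data flow

The package implements a two-sample Mendelian randomization analysis of
log₂-transformed CRP on CRC survival. The two "samples" are an exposure
cohort (population-based, with genotypes, covariates and serum CRP) and an
outcome cohort (CRC patients followed from diagnosis to death or
administrative censoring). The stages are: per-variant exposure scan →
instrument selection (MAF ≥ 0.05, p < 5×10⁻⁸, greedy LD clumping at
r² < 0.001 within 10,000 kb, discovery/replication, pooled re-estimation) →
per-variant additive-hazards outcome scan → summary-statistic MR →
GRS analysis → power. A packaged seven-variant instrument table carries the
published per-SNP summary statistics, so the summary-statistic stages can be
reproduced on a desk scale without any cohort data.

## Additive-hazards regression

Outcome associations use λ_i(t) = λ₀(t) + βᵀZ_i with constant β (the
Lin–Ying estimator). The closed form is β̂ = A⁻¹b with A the risk-set
scatter integrated over follow-up and b the event sum of covariate
deviations from the at-risk mean; the variance is the sandwich A⁻¹BA⁻¹ with
B the event sum of squared deviations. Implementation notes:

- Tied event times are treated as simultaneous: the risk-set mean at a tied
  time includes every tied subject (suffix statistics are read at the first
  occurrence of each time value).
- Integration stops at the largest observed time; entry time is 0 for all
  (diagnosis is the time origin; no left truncation).
- Only the robust variance is exposed. A is scaled to correlation form for
  the rank check, and rank-deficiency errors name the offending columns.
- Cause-specific analyses recode deaths from other causes as censoring at
  the death time; an event with a missing cause code is an error, not a
  silent exclusion.

The estimator is verified against a brute-force oracle that enumerates the
risk-set integrals explicitly (agreement to 1e-10 on small instances), and
against the slope of lifelines' nonparametric Aalen cumulative-coefficient
curve on large simulated data.

## MR estimators

Instruments are oriented so every exposure beta is positive (outcome effect
sign-flipped in tandem; Wald ratios are invariant). Outcome SEs absent from
the inputs are recovered from two-sided p-values as |estimate|/z(p), with
z(p) computed by scipy's inverse survival function (stable to p ≈ 1e-300).
Because printed p-values carry 3 significant figures, estimates recomputed
from them carry rounding noise of order ±0.05 per 1,000 PY on this table.

- **IVW**: weighted mean of ratios with first-order weights b_X²/se_Y².
  Default SE is multiplicative random-effects, (Σw)^(−1/2)·max(1, √(Q/(J−1))):
  the fixed-effect SE (≈4.0 here) is too small to reproduce the published
  interval, while the random-effects SE (≈5.7) matches it, so that is the
  default. The point estimate is identical under both.
- **Medians**: the weighted median interpolates the standardized
  mid-cumulative weight distribution at 0.5 (an exact 0.5 tie returns the
  bracketing ratio); the simple median is the equal-weight special case,
  which for seven instruments is the middle order statistic. SEs come from a
  parametric bootstrap (default 10,000 draws, explicit seed) resampling both
  b_X and b_Y from their normal distributions; CI = estimate ± 1.96·SD.
- **MR-Egger**: WLS of b_Y on b_X with intercept, weights 1/se_Y². The
  intercept is the average directional pleiotropic effect per variant; its
  test is the pleiotropy check. Default inference uses the normal reference
  with the same floored multiplicative scale as IVW — this reproduces the
  published intervals exactly. Because that convention is anticonservative
  for small instrument counts when pleiotropy dominates, `dist="t"` switches
  to the exact WLS small-sample inference (un-truncated scale, t with J−2
  df), which simulation shows holds the 5% level; the calibration tests use
  it.
- Wald-ratio SEs are first-order (se_Y/|b_X|), ignoring exposure-side
  uncertainty — appropriate with minimum instrument F ≈ 61; a second-order
  option exists but is off by default.

All results are on the HD-per-1,000-person-years-per-doubling scale; the
doubling interpretation is automatic because exposure is log₂-transformed.

## Synthetic cohorts

The generator's defaults are the emulated study's conditions: seven
independent Hardy–Weinberg variants at the fixture allele frequencies with
the fixture effect sizes; instruments explaining 4.0% of exposure variance;
an outcome cohort of 6,460 subjects followed 8 years with baseline hazard
−ln(1−0.414)/8 ≈ 0.0668/PY so the all-cause death fraction matches the
emulated cohort's 41.4% (the related constant 0.052/PY is the person-year
averaged rate 2,676/(6,460×8), used as λ₀ in the power scenario); and a
0.606 cause-of-interest share of deaths. Choices made where the emulated
design is silent:

- Exposure noise is calibrated from the empirical variance of the realized
  genetic score, so the target R² is met under LD too (where no closed form
  for copula dosage covariances exists). Scaling all SNP effects by a
  common factor rescales the noise and leaves R² unchanged.
- Optional LD uses a Gaussian copula with AR(1) latent correlation within
  blocks; the realized dosage correlation is slightly below the latent one,
  so calibration tests bound rather than pin it.
- Survival is exponential given the subject's hazard λ₀ + θ·(X − X̄) (the
  predictor is centered so λ₀ stays the population-averaged rate), with
  purely administrative censoring; negative hazards are clamped at a
  configurable floor (default 1e-6/PY) and the clamped fraction is recorded
  and warned about above 1%. Competing causes are assigned by independent
  thinning, which is sufficient for cause-specific censoring semantics but
  does not model correlated cause-specific hazards.
- Covariates default to age ~ N(57, 8), sex ~ Bernoulli(0.5) and ten
  standard-normal PC columns with zero effects unless configured.
- All randomness flows from one seed through `SeedSequence.spawn` in a
  fixed stage order, so a config and seed reproduce a cohort bit for bit.

What passing tests on these cohorts do **not** show: robustness to
population structure, imputation uncertainty, array batch effects,
non-administrative censoring, or correlated competing risks — none of
which the generator emulates.

## Exposure GWAS conventions

Normal-approximation p-values (the intended n ≈ 5×10⁴ makes the t
correction negligible); strict inequality for p < 5×10⁻⁸ and retention at
MAF = 0.05 exactly; clump ties at equal p broken by genomic coordinate;
missing dosages handled per-variant complete-case. The replication rule —
direction consistency plus replication p < 0.05/n_candidates — is a
package choice; joint variance explained is computed on covariate-
residualized exposure. Two F-statistic conventions are provided (squared
Wald z, and (n−2)R²/(1−R²)) because published single-number Fs do not
always state theirs.

## GRS

The score is the weighted **mean per non-missing marker** (PLINK's profile
convention), weights being the pooled exposure betas. Quintiles are
rank-based with stable tie-breaking (sizes within one of n/5); the survival
model uses indicators for quintiles 1, 2, 4, 5 with the middle quintile as
reference, and the per-SD analysis standardizes the score over subjects
with at least one observed marker.

## Power

The analytic route treats death as binary: two-sided power
Φ(−z_{α/2}+ν) + Φ(−z_{α/2}−ν) with ν = |log OR|·√(n·R²·p(1−p)); it is
deterministic and conservative for censored data. The simulation route
draws a standardized instrument score (the GRS limit of many small
instruments, rather than seven discrete SNPs — the minimal scenario that
matches a variance-explained parameterization), builds unit-variance
exposure with the stated R², simulates additive-hazards survival, and
tests the Lin–Ying coefficient on the score; 1,000 replicates by default,
reported with binomial Monte-Carlo SE. At the planning scenario
(n = 6,460, λ₀ = 0.052/PY, 8 years, R² = 0.04, effect 0.026/PY per
exposure SD, α = 0.05) about 2.3% of subjects sit more than 2 SD below the
mean and have their hazards clamped at the floor; the run carries a warning
flag for this.

## Problem sizes used in tests

The shared GWAS fixture cohort uses n = 50,000; pipeline parameter-recovery
replicates use the study-scale n = 59,605 exposure / 6,460 outcome with 200
null and 100 non-null replicates; calibration tests (scan p-value
uniformity, Egger type-I error) use 200–1,000 replicates at reduced n.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping the default suite fast.

## Known limitations

- No Cox or Fine–Gray models, no time-varying coefficients in reported
  output, no left truncation.
- No MR-PRESSO, mode-based or multivariable MR estimators; no Steiger
  filtering; no external pleiotropy-database lookup.
- Instrument harmonization assumes both samples report the same effect
  allele per variant (single-consortium setting); there is no
  allele-frequency-based strand inference.
- Median-estimator p-values use the normal approximation to the bootstrap
  SD, not bootstrap percentiles.
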