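# Methods

This note documents the statistical procedures camnorms implements, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Scaled scores (quantile normalization)

Raw scores are oriented so that higher = better (timed/error measures are
negated), assigned mid-rank plotting positions `q = (rank − ½)/n` with ties
sharing their mid-rank, mapped through the standard normal quantile
function, scaled to mean 10 / SD 3, rounded half-away-from-zero and clamped
to the integer range 1–19. Choices:

* **Quantile estimator.** The mid-rank position `(rank − ½)/n` is the
  standard symmetric plotting position; it keeps the scaled-score
  distribution symmetric and never produces q ∈ {0, 1}. Other conventions
  (e.g. `rank/(n+1)`) would shift extreme bins by at most one scaled-score
  unit; since the raw normative data behind the built-in tables are not
  distributed, exact reproduction of the published bin edges from data is
  not attempted — the published tables are transcribed, not refit.
* **Rounding.** Half-away-from-zero, so 10 + 3z = 11.5 → 12. Note that
  rounding makes the SS 7–13 band correspond to |z| < 7/6 (normal mass
  0.757), wider than the continuous ±1 SD band.
* **Bins.** Per scaled score, the bin is the min/max observed raw value.
  Extreme bins are widened to the instrument floor/ceiling so the lookup is
  total; out-of-range raw values clamp to the extreme bin with a warning
  (the published floor/ceiling bins bound the observed range and are
  open-ended in spirit).
* **Sparse levels.** Interior scaled scores that attract no sample value
  receive an equal share of the unobserved raw gap between their observed
  neighbours (a single gap with no missing level splits at the midpoint).
  When adjacent observed raw values straddle levels more than one step
  apart, the fill borrows spare width from the neighbouring bins; a sample
  too sparse even for that is refused. Construction requires n ≥ 20,
  values within the instrument range, and a non-constant sample.

## Demographic correction (MFP regression)

Scaled scores are modelled as a Gaussian linear function of age, education
and the male indicator. Continuous covariates are standardized to
`t = (x + shift)/scale` with `shift = 1 − floor(min x)` when `min x ≤ 0`
(else 0) and `scale` the power of ten nearest the observed range on the log
scale — for education in years this yields `(edu + 1)/10`, for age
`age/100`. Each continuous covariate may enter as a fractional polynomial
with powers from {−2, −1, −½, 0, ½, 1, 2, 3} (0 = natural log; a repeated
power p contributes `t^p` and `t^p ln t`), selected by the closed testing
procedure: best FP2 vs null (4 df), vs linear (3 df), vs best FP1 (2 df),
using deviance differences `n·ln(RSS_reduced/RSS_full)` on chi-squared
reference distributions. Covariates are visited most-significant-first and
cycled until the selection stabilizes (max 5 cycles).

* **Selection level.** α = 0.05 by default. Continuous covariates may be
  dropped entirely; the male indicator is always retained linearly so the
  emitted formula always carries a male term, however small.
* **Estimation.** Ordinary least squares; the residual SD uses the fitted
  model's residual degrees of freedom. T-scores are
  `50 + 10·residual/resid_sd`, so they have mean exactly 50 on the fitting
  sample and SD `10·√((n−p)/(n−1))` ≈ 10.
* **Emission.** Linear (or dropped, as zero-slope) shapes are re-expressed
  on the canonical `(edu+1)/10`, `age/100` basis regardless of the
  sample-driven shift/scale, adjusting the intercept; non-linear shapes
  cannot be expressed as a single linear formula and raise, with
  `predict()` as the general path.
* **Bootstrap stability.** Subjects are resampled with replacement K times
  (default 1000) and the full selection-and-fit rerun; the report tabulates
  selected-power frequencies per covariate and coefficient percentiles over
  the replicates whose shapes are linear-representable. Replicate r draws
  from an independent stream spawned from the seed, so reports are
  reproducible and K can be changed without reshuffling earlier replicates.
* **Empirical size.** The closed test is conservative here: with pure-noise
  covariates at n = 400, both continuous covariates are dropped in ~95% of
  replicates at α = 0.05 (the 4-df referencing of the best-of-36 FP2
  comparison over-covers, particularly for age, whose restricted 18–64
  range limits the distinguishability of the power transforms).

## Scoring and impairment

T-scores are kept unrounded internally (CSV export rounds to 1 decimal).
Deficit scores bin T in 5-point steps: 0 for T ≥ 40, 1 for [35, 40), 2 for
[30, 35), 3 for [25, 30), 4 for [20, 25), 5 for T < 20. The endpoints
(0 ⇔ T ≥ 40, 5 ⇔ T < 20) define the published scheme; the interior
boundaries follow the standard global-deficit-score convention. They do not
affect binary impairment, which only asks whether deficit ≥ 1 (T < 40) per
measure, or whether the domain mean deficit exceeds 0.5 — with four
executive tests that requires at least three mildly impaired members when
deficits are binary. Domain composites are complete-case: a missing member
test suppresses the domain T-score, deficit and impairment flag, mirroring
per-measure complete-case handling of missing data. Demographics outside
age 18–64 or education 0–20 flag the record as an extrapolation but do not
refuse scoring.

## Synthetic cohorts

The generator emulates the two-group study structure the analysis assumes:

* **Demographics.** Age ~ truncated normal on [18, 64] (34.6 ± 10.5
  seronegative, 37.9 ± 9.38 seropositive), education ~ truncated normal on
  [0, 20] rounded to integer years (12.4 ± 4.23 vs 9.65 ± 3.78), male ~
  Bernoulli (34.7% vs 22.2%). Education truncation bounds cover plausible
  schooling; only mean/SD are published.
* **Scores.** Expected scaled score from the generative coefficients, plus
  Gaussian noise `resid_sd·(0.4·f + √(1−0.16)·ε)` where f is one shared
  subject factor — the within-subject correlation across the seven measures
  is unreported, so a single common factor with loading 0.4 is assumed
  (flagged here; it matters for domain-composite variances, not for
  per-measure means). Seropositive subjects are shifted by `d·resid_sd` per
  measure, which targets Cohen's d of d on the T-score scale because the
  within-group T SD is ≈ 10; integer rounding of scaled scores attenuates
  the measured d by under 1%. The default effects are the published
  per-measure values (WCST −0.39, CTT2 −0.21, …). Raw values are drawn
  uniformly within the scaled-score bin, so scoring with the generative
  norms returns exactly the generated integer scaled score.
* **HIV covariates.** CD4 is log-normal with (μ, σ) least-squares matched
  on the log scale to the published median 407 and IQR (246, 574) — the
  three quantiles are not exactly log-normal-consistent, so each is
  reproduced to within ~5%. Detectable viral load is Bernoulli(0.433) with
  log₁₀ VL ~ N(4.59, 1.28²) when detectable; cART Bernoulli(0.551);
  genotype classes AG/AG-plus/non-AG with probabilities 0.59/0.149/0.261,
  drawn independently of scores. An optional hook shifts scores by genotype
  class (off by default) to emulate the reported genotype contrast.
* **Not emulated.** Missing-data patterns (every simulated subject
  completes all seven tests), practice/testing-order effects, real raw
  score distributions within bins, longitudinal follow-up, and any
  covariate-score dependence beyond the configured group and genotype
  shifts. Passing recovery tests therefore demonstrates the internal
  consistency of the pipeline under its own generative assumptions, not the
  field validity of the norms.

## Group statistics

Cohen's d uses the pooled SD and the normal-approximation CI
`d ± 1.96·√((n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀)))`; t-tests are pooled-variance
two-sided (Student, not Welch). Odds ratios are computed from the 2×2
table — identical to the MLE of a one-predictor logistic regression — with
a Wald CI by default and a profile-likelihood CI (deviance inversion with
the reference log-odds profiled out) as an option: the published intervals
are not exactly reproduced by the 2×2 Wald formula and are closer to
profile-likelihood intervals, so only point estimates are treated as
reproduction targets. Zero cells use the Haldane–Anscombe 0.5 correction
(flagged); a zero margin is refused. Fisher's exact test is the standard
two-sided sum of hypergeometric probabilities no larger than the observed
table's. No multiple-testing correction is applied anywhere, matching the
original analysis. Built-in stratifiers: serostatus, cART vs naïve,
CD4 ≥ 350 vs < 350, undetectable vs detectable viral load, and AG vs
(AG-plus ∪ non-AG) genotype.

## Problem sizes used in checks

The recovery checks use sizes chosen to keep Monte-Carlo error well inside
the asserted tolerances: norm refitting uses 50 replicates of n = 400
normative samples (matching the order of the real normative group); effect
recovery uses 5000 per group (SE(d) ≈ 0.02 against a ±0.05 band) and null
recovery 2000 per group; the exact-test oracle enumerates all 2×2 tables
with total n ≤ 40; bootstrap stability examples use K = 200.

## Known limitations

* The built-in conversion tables are transcriptions; the instrument
  ceilings are inferred from the printed extreme bins (e.g. Stroop 133),
  not from instrument manuals.
* Interior deficit-score boundaries and the scaled-score quantile
  convention of the original in-house scripts are unstated in the source;
  the standard conventions adopted here are documented above.
* The MFP implementation covers the Gaussian case only (no GLM/survival
  variants, no spline alternatives, no missing-demographics imputation).
* T-scores for demographics outside the normative ranges are
  extrapolations and flagged as such.
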