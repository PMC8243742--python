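# Methods

## The problem

Safety screens in two-arm randomised trials collect many continuous
laboratory and clinical outcomes (blood counts, electrolytes, liver
enzymes) at repeated visits.  Standard practice dichotomises each
outcome at its reference-range thresholds and compares the proportions
of participants with abnormally low or high values — usually with
Fisher's exact test or a Wald interval for the difference in
proportions.  Because abnormality thresholds sit in the tails, observed
event counts are tiny, these comparisons are badly underpowered, and
with zero events in both arms they are not even estimable.  Real safety
signals are missed.

## Distributional differences in proportions

Instead of counting events, the distributional approach fits a
distribution to each arm's continuous values and reads the abnormal
proportion off the fitted CDF.  For the normal model with a common SD
`s` (pooled, `n_t + n_c − 2` denominator), arm `a`'s below-threshold
proportion and its delta-method standard error are

    p_a  = Φ((x0 − x̄_a) / s)
    se_a = (s / √n_a) · f_a(x0),     f_a = N(x̄_a, s²) density,

and the between-arm difference is `d = p_t − p_c` with
`se(d) = √(se_t² + se_c²)`.  The SE captures the sampling variability of
the arm means only; the pooled-SD estimation noise moves both arms'
proportions together and largely cancels in `d`, which is why the
delta-method SE is honest for the difference (verified by Monte-Carlo
calibration below).  Because `d/se(d)` is, to first order, proportional
to the two-sample mean-comparison z-statistic, the comparison of
proportions retains the precision of the comparison of means: the
closed-form ratio of the two z-statistics stays within 5% of 1 for
standardised shifts up to 0.3 at n ≥ 200/arm, and the power advantage
over Fisher's exact test at a 5th-percentile threshold is large (e.g.
0.74 vs 0.19 at n = 60/arm for a 0.5-SD shift).  The method also returns
a positive SE when both arms have zero observed events, where Fisher is
non-estimable and the Wald interval collapses to a point.

Three variants cover the distribution shapes met in practice:

* **normal, equal variance** — as above;
* **normal, unequal variance** — the arms' spreads are linked through
  the variance ratio `R = σ_t²/σ_c²`:
  `s_uneq² = ((n_t−1)s_t² + (n_c−1)R s_c²)/(n_t+n_c−2)`; the treated arm
  uses variance `s_uneq²`, the control arm `(s_uneq/√R)²`, and each
  arm's delta-method term uses its own density and sample size.  `R = 1`
  collapses exactly onto the equal-variance method.  `R` should come
  from prior studies where possible; when estimated from the data the SE
  understates the true variability (measured calibration ratio ≈ 0.72
  at Glass's Δ = 1 versus ≈ 0.98 with `R` known), which is why a
  configurable SE correction multiplier (default 1.0, applied only when
  `|Δ| > 0.75`) is provided and always surfaced in the result flags;
* **skew-normal** — location ξ, scale ω > 0, shape α, fitted by the
  method of moments from (mean, SD, skewness).  The skewness of a
  skew-normal is bounded by ≈ ±0.9953, so sample skewness is clamped to
  ±0.99 before inversion (flagged `skewness_clamped`); this matters
  because the selector routes all |skewness| ≥ 1 outcomes here.  The CDF
  is evaluated through `scipy.stats.skewnorm` (Owen's T function).

### Pooling in the skew-normal difference

The skew-normal difference models the treatment effect as a pure
location shift, exactly like the equal-variance normal method: by
default both arms share the pooled SD and the n-weighted average of the
per-arm skewness coefficients, and only the locations differ.  This is a
deliberate design choice, made after Monte-Carlo calibration: with fully
per-arm fits the location-only delta SE ignores the (large) sampling
noise of each arm's shape and scale estimates and is miscalibrated
(mean reported SE ≈ 0.62 × the empirical SD of `d` at a 5th-percentile
threshold, α = 4, n = 500/arm), whereas with shared shape and scale that
noise cancels between arms (ratio ≈ 0.98 at a 10th-percentile threshold,
≈ 1.00 under the null).  A `pooled=False` option retains per-arm fits
for sensitivity analyses, with the caveat that its SE is optimistic.
Calibration degrades in the extreme thin-side tail of a strongly skewed
fit (ratio ≈ 0.91 at the 5th percentile); users screening heavily skewed
outcomes with deep-tail thresholds should treat borderline p-values with
caution.

## Covariate adjustment

Trials should adjust the treatment effect for randomisation
stratification variables.  The extension fits a linear model
`Y = β0 + β_A·A + β_X·X + ε` by OLS (or a two-level random-intercept
model by REML), takes each arm's *marginal mean* — the model prediction
with every covariate at its overall sample mean, categorical covariates
at their sample proportions — and feeds the marginal means through the
same machinery with `sd_total = √(σ_e² + σ_a²)` in the CDF
(σ_a² = 0 for OLS) and `σ_e/√n_a` scaling the density in the SE.  With
no covariates this reduces exactly (to 1e−10) to the unadjusted
equal-variance method.  The p-value reported for the adjusted
distributional difference is the treatment coefficient's p-value from
the model — the adjusted proportion difference carries the precision of
that coefficient — while the delta-method Wald p is kept in the result
details.  A skew-normal residual family replaces the normal CDF/density
by a skew-normal matched to the model residuals' skewness.  The
coefficient CI uses the normal quantile, consistent with the
delta-method normal reference used throughout.

## Automated method selection

With tens of screened outcomes, per-outcome model choice by hand is
impractical.  The selector gates on the observed data, in order:

1. if the skewness statistic (by default the per-arm coefficient of
   larger magnitude; an n-weighted pooled variant is configurable) has
   |skewness| ≥ 1 → skew-normal method (boundary inclusive);
2. otherwise a two-sided variance-ratio F test
   (`F = s_t²/s_c²`, df `(n_t−1, n_c−1)`, doubling the smaller tail):
   p < 0.05 → unequal-variance method, p ≥ 0.05 (boundary inclusive)
   → equal-variance method.

Glass's `Δ = (x̄_t − x̄_c)/s_c` independently flags large effects
(|Δ| > 0.75), the regime where the data-estimated unequal-variance SE is
optimistic and the correction multiplier applies.  All three cutoffs
(1, 0.05, 0.75) are configuration-exposed defaults.

Running the selector across many outcomes over-identifies skewness and
unequal variance (each gate has its own false-positive rate), so the
pipeline logs a per-run selection tally.  The consequences are
asymmetric: a false skew-normal selection fits a small skewness
coefficient and behaves like the normal method, but a false
unequal-variance selection treats a chance SD imbalance as real
population structure, which at tail thresholds manufactures an apparent
proportion difference.  Measured at n = 100/arm with a 5th-percentile
threshold over 10,000 null replicates, the equal-variance test rejects
at 0.042, while the selector composite rejects at ≈ 0.079 — essentially
all of the excess coming from the ~5% of replicates where the F test
falsely fires.  Equal variance is therefore the deliberate default
whenever the evidence is borderline, and operating-characteristic
summaries report the fixed-method and selector-composite rates
separately.

## Empirical comparators and conventions

* Dichotomisation uses strict inequalities (`value < low`,
  `value > high`); values equal to a threshold are normal, since
  reference ranges are inclusive normal intervals.  The convention is
  configuration-exposed because published analyses rarely state it.
* Fisher's exact test: two-sided by minimum likelihood (sum of
  hypergeometric point masses no larger than the observed table's),
  cross-checked against exhaustive enumeration; a doubling convention is
  selectable.  Zero events in both arms → non-estimable (NE).  Tables
  with a single zero cell remain estimable.
* Wald difference in proportions: unpooled SE, z = 1.959964, no
  continuity correction.  Zero events in both arms give the degenerate
  0.00 [0.00, 0.00], flagged so the apparent certainty is never read as
  evidence.
* Signal counting: p < α for test-based criteria, CI excluding zero for
  the interval criterion; NE and degenerate results never count.
  No multiplicity adjustment is applied, by design — outputs are
  *signals* for follow-up, and the report header states the number of
  tests performed.

## Screening pipeline

Per outcome × tail: reduce repeated measures to an endpoint value per
subject (default: last observed visit, so a missing final visit falls
back to the previous one rather than dropping the subject), dichotomise
and run the empirical comparators, fit the covariate-adjusted model,
let the selector choose the distributional method, and emit one row.
When the selector chooses skew-normal, the adjusted pathway uses the
skew-normal residual family; when it chooses unequal variance, the
adjusted columns fall back to the equal-variance residual model with a
note (adjustment composes only with the normal and skew-normal residual
families) and the unadjusted unequal-variance estimate is kept in the
row details.  Analysis is as-allocated by the arm column; missing values
are excluded listwise per outcome-tail, with no imputation.  Zero-variance
outcomes produce rows whose distributional columns are marked
non-estimable while the empirical columns survive.

## Synthetic trials

The generator emulates the structure the methods assume: two parallel
arms (defaults for the bundled small-trial preset: 66 treated vs 61
control, matching a small severe-asthma trial), ten continuous outcomes
spanning normal, skew-normal and lognormal shapes with low-tail
thresholds producing event rates from 0 to ~40%, a categorical and a
binary stratification covariate with additive effects, a visit schedule,
and MCAR missingness.  Per-outcome, per-arm random substreams are
derived from the master seed, so adding an outcome never perturbs the
others.  Skew-normal generation uses the same moment map as the fitting
code, making recovery tests self-consistent; the lognormal family
(skewness solved from `(w+2)√(w−1) = γ1`, `w = e^{σ²}`) exercises the
|skewness| ≥ 1 route.

What the generator does **not** model, and hence what passing tests do
not establish about real trial data: within-subject correlation across
visits (visits are independent draws — a latent-subject variant was
rejected because summing draws attenuates the target skewness by √2 and
breaks the generator's moment contract), informative or visit-dependent
missingness, measurement rounding/detection limits, non-adherence and
treatment crossover, and between-outcome correlation.

Operating-characteristic problem sizes used by the test-suite and the
reproduction script: SE calibration 2,000 replicate trials per method at
n = 200–500/arm; type-I error 10,000 null replicates at n = 100/arm with
a 5th-percentile threshold; power ordering 5,000 replicates at
n = 60/arm with a 0.5-SD shift; selector recovery 300 replicates per
family at n = 500/arm.

## Numerical choices and degenerate inputs

* Skewness: population-moment coefficient `b1 = m3 / m2^{3/2}`,
  computed on standardised values for numerical stability; a
  small-sample-adjusted variant (`√(n(n−1))/(n−2) · b1`) is behind a
  flag, off by default.
* Zero-variance arms refuse distributional analysis with an explicit
  error rather than returning proportions of exactly 0 or 1.
* `se = 0` with `d = 0` yields the degenerate point interval with p = 1
  and a flag; `se = 0` with `d ≠ 0` is an error.
* Moment inversion for the skew-normal caps |δ| at 0.999999 to keep the
  shape finite at the clamp boundary.
* Report rendering: estimates and intervals at 2 decimal places,
  p-values below 0.01 as "< 0.01" and above 0.99 as "> 0.99", NE spelt
  literally; the machine-readable CSV always retains full precision.

## Known limitations

* No method supports skewed data with unequal variances; the selector
  never composes the two.
* The unequal-variance SE with data-estimated R is optimistic for large
  effects; the correction multiplier's validated magnitude is not
  built in and must be supplied by the user.
* The adjusted pathway offers normal and skew-normal residual families
  only (no gamma), and marginal means are evaluated at covariate means
  rather than averaged over predictions.
* The pipeline reports two arms only; more than two exposure levels are
  out of scope.
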