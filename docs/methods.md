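# Methods

## The task

`tempodisc` implements a unified monetary delay-discounting task and its
full analysis chain. A participant repeatedly chooses between a hypothetical
immediate amount and a fixed delayed amount of EUR 40. Six delays are
probed — 2 days, 2 weeks, 1 month, 3 months, 6 months and 1 year, mapped to
2, 14, 30, 90, 180 and 360 days — each in a block of five choices, with
block order randomized per session.

Within a block the immediate offer follows an adjusting-amount (bisection)
staircase: the first offer is EUR 20, a "delayed" choice raises the next
offer and an "immediate" choice lowers it, and the adjustment halves every
trial (10, 5, 2.5, 1.25, 0.625 EUR at defaults). The offer that would
appear on the sixth trial is the indifference point — the staircase's
estimate of the delayed reward's subjective value at that delay. Offers are
kept at full floating precision; the sixth-offer definition requires
fractional values and rounding would break the exact bisection arithmetic.
For any deterministic chooser with a fixed subjective value `s`, the
staircase pins the indifference point to within
`(40 − 20)·2⁻⁵ = 0.625` EUR of `s`; the test suite asserts this bound by a
brute-force sweep of `s`.

## Discounting indices

From a profile of six indifference points (expressed as fractions
`SV ∈ [0, 1]` of the delayed amount) the package computes:

* **Hyperbolic k** — `SV = 1/(1 + kD)`, `D` in days.
* **Exponential k** — `SV = e^(−kD)`.
* **AUC** — area under the empirical discounting curve: delays normalized
  by the maximum delay (360 days), subjective values by the delayed
  amount, trapezoid areas `(x₂−x₁)(y₁+y₂)/2` summed over successive
  points. The curve is anchored at `(0, 1)` by default so the AUC spans
  the full `[0, 1]` range (a non-discounter scores exactly 1); the anchor
  is a switch (`anchor_at_zero=False`) for comparison with conventions
  that omit it.
* **Inconsistent preferences** — count of adjacent-delay pairs where the
  subjective value *rebounds* by at least 20% of the delayed reward
  (`R2 ≥ R1 + R/5`, i.e. +8 EUR at defaults), on raw currency values.

Both `k` fits minimize the sum of squared residuals over `ln k`. The
optimizer is a coarse global grid (`ln k ∈ [−12, 2]`, 141 points) followed
by bounded local refinement to `|Δln k| < 10⁻⁶`; the single-parameter SSE
surface can be multimodal in pathological profiles and the global grid
removes any initialization sensitivity. The same dense grid, at step
`10⁻⁴`, is the independent oracle in the tests. Rates are floored at
`k = e⁻¹²` (≈ 6·10⁻⁶/day) so `ln k` stays finite; a profile that is exactly
flat at `SV = 1` shows no measurable discounting and is reported at the
floor with zero residuals — the `k → 0` limit. `R²` is
`max(0, 1 − SSres/SStot)` about the mean observed `SV`; when
`SStot < 10⁻¹²` (constant profiles) `R²` is 1 if the residuals also vanish
and 0 otherwise. `log_k` is the natural logarithm throughout — the scale of
the packaged norms, whose stratum medians sit near −4.

## Normative tables

Percentile equivalents are type-8 sample quantiles (Hyndman–Fan), the
median-unbiased choice: linear interpolation of order statistics at
plotting positions `p_k = (k − 1/3)/(n + 1/3)`, clamping to the sample
minimum/maximum outside the covered range. Tables are stratified by sex
(F/M) and three education levels — 3–8, 9–13 and 14–23 years of schooling;
years outside 3–23 are rejected because the norms are undefined there. Age
is not a stratification variable: the normative study found no age effect.

The packaged registry `"italian_2022"` ships the published Italian
normative tables (357 healthy adults) for natural-log hyperbolic k and
AUC at levels 5, 10, 25, 50, 75, 85, 90, 95, as two checksummed CSVs.
Classification flags extreme performances with *strict* inequalities
(a score exactly at a threshold is typical): log-k below the stratum's
10th percentile (or AUC above the 90th) is extremely **low** discounting,
log-k above the 90th (or AUC below the 10th) extremely **high**. The
source publication's prose examples quote the 5th/95th thresholds while
stating a 10th/90th rule; both levels are in the tables and the bounds are
arguments (`low_level=`, `high_level=`), so either convention is available
and neither is silently corrected.

`distribution_ic` reproduces the distribution screen used before the group
models: Gaussian vs Cauchy maximum likelihood, compared by
`AIC = 4 − 2 ln L` and `BIC = 2 ln n − 2 ln L` (both families have two
parameters, so `BIC − AIC = 2(ln n − 2)` identically).

## Validity statistics

All inference is implemented from first principles, with scipy, sklearn
and statsmodels serving only as cross-check oracles in the tests:

* **ROC / Youden** — cutoffs at every distinct observed score plus a
  sentinel; a score ties on the positive side (weak inequality); AUC by
  the trapezoid rule over (FPR, TPR), which equals the Mann–Whitney
  probability `U/(n₁n₂)` with ties counted one-half. The Youden optimum
  maximizes `TPR − FPR`; ties break toward lower FPR, then the smaller
  cutoff. The clinical group is the positive class; direction is
  `higher_is_positive` for log-k and `lower_is_positive` for AUC (steeper
  discounting is the pathological pole).
* **Wilcoxon rank-sum** — midranks, tie-corrected normal variance,
  ±0.5 continuity correction; reports the Mann–Whitney `U` of the first
  sample.
* **Group model** — the published "generalized linear model" reports F
  statistics and partial η², i.e. ordinary least squares; implemented as a
  Gaussian linear model with drop-one (partial) F per term via QR, with
  education as a 3-level factor and sex as a 2-level factor. Without
  interactions, drop-one sums of squares coincide with Type-III.
  `partial η² = SS_term/(SS_term + SS_residual)`.
* **Bartlett** — `K²` with the standard correction factor against
  `χ²(g−1)`.

## Synthetic cohorts

Simulated participants stand in for human data so the whole chain is
testable offline. True rates are log-normal: `ln k ~ Normal(μ_stratum, σ)`,
matching the empirical observation that log-transformed k is normally
distributed. Defaults encode the normative study conditions:

* stratum frequencies from the published demographics (187 M/170 F;
  education 102/128/127 of 357), treated as independent margins;
* stratum means at the published stratified log-k medians (−2.70 to −4.35);
  σ = 2.27, the normative-group SD;
* ages uniform within the three published bands (21–39/40–59/60–92) at the
  printed band frequencies, with no effect on k (none was found);
* the case-control generator draws ln k from N(−2.33, 1.59) for the
  clinical (mOFC-lesion) group vs N(−3.79, 2.27) for controls — the
  published group moments.

Choices are value-based with logistic noise:
`P(delayed) = logistic((40·SV(k,D) − immediate)/temperature)` mixed with a
`lapse` probability of a uniformly random response. Human choice-noise
magnitude is unknown, so the defaults are a calibration: temperature
4.0 EUR with lapse 0.05 reproduces the normative sample's noise
fingerprint — simulated median hyperbolic R² ≈ 0.75 vs exponential ≈ 0.62
(published: 0.75 and 0.64) and ≈ 0.27 mean inconsistent preferences
(published: 0.30). This is calibration, not ground truth: the simulator
emulates stationary softmax noise and has no fatigue, magnitude effects,
time-of-day or comprehension failures, so passing tests show the analysis
chain is correct, not that real humans behave this way.

With these group moments the Gaussian overlap predicts a ROC AUC of
`Φ(1.46/√(1.59² + 2.27²)) ≈ 0.70` on true ln k; the simulated end-to-end
pipeline (staircase + fit, with choice noise) lands at ≈ 0.70, consistent
with the 0.73 reported for the real clinical sample.

Reproducibility: each cohort is driven by one integer seed; per-participant
seeds derive from it by `numpy` seed-sequence spawning, so cohorts are
bitwise reproducible and participants are independent streams.

## Problem sizes and numerical choices

The test suite and the acceptance script use: a 1500-point sweep for the
staircase convergence bound; 1000 random instances for the type-8 quantile
cross-check (tolerance 10⁻¹⁰); 100 seeded profiles against the 10⁻⁴-step
grid oracle (SSE slack 10⁻⁶); 200 small instances for the exact ROC/
Mann–Whitney identity; 40 noiseless agents over `k ∈ [0.001, 0.3]` for the
recovery bound `|ln k̂ − ln k| ≤ 0.15` (staircase quantization is the only
error source; observed worst error ≈ 0.06); 10⁴ participants per group for
the case-control ROC (asserted band [0.65, 0.75]); and 500 null
simulations for the 5% type-I calibration of the ANCOVA F and Bartlett
tests (accepted band [0.03, 0.07], ±2 binomial SDs).

Degenerate inputs fail loudly rather than silently: profiles need two
distinct delays to fit, constant data is rejected by the Cauchy MLE and
Bartlett, empty groups by the ROC, rank-deficient designs by the ANCOVA
(naming the aliased columns), and session logs are validated by exact
staircase replay (any offer inconsistent with the logged choices raises an
error naming the row).

## Known limitations

* Norms are the published Italian tables; no other populations, and no
  regression-based continuous norming.
* Only the two single-parameter discount families are fitted — no
  quasi-hyperbolic β-δ or Green–Myerson exponent, and no magnitude effects.
* The real clinical sample's statistics (e.g. ROC AUC 0.73, Youden cutoffs)
  require the original dataset; the package supports scoring such data via
  the session-log reader but does not assert those numbers.
* The choice-noise model is stationary; it does not emulate drifting
  attention or response-time structure.
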