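# Methods

## Overview

`locotrack` quantifies the early-life locomotor activity of individually
tagged broiler chickens from passive-RFID floor-antenna registrations and
relates it to growth. The pipeline has four layers:

1. **Ingestion and cleaning** (`rfid_io`): parse (timestamp, tag, antenna)
   logs, exclude group-level sensor outages and handling periods, and clip
   to the main light period.
2. **Kinematics** (`kinematics`): convert antenna registrations to
   approximate distances moved and a daily average distance moved per hour
   (DADM).
3. **Descriptors** (`descriptors`): reduce each bird's two-week daily
   activity series (ages ≤ 15 d) to five scalars — MD, Skew, RMSE, AC, ENT.
4. **Statistics** (`stats`): Kendall rank correlations with bootstrap CIs,
   Wilcoxon comparisons of ADG quartile groups, and a sum-to-zero linear
   model of average daily gain (ADG) reduced by backward stepwise F-tests.

A calibrated simulator (`synthetic`) generates registration logs, weight
tables and round metadata with known generating parameters, so every layer
is validated by parameter-recovery experiments (`evaluation`) rather than
by reference to any particular farm dataset.

## Cleaning rules

* **Group-level gaps.** An interval strictly longer than 300 s with no
  registration from *any* tag is sensor downtime and is excluded exactly
  (from the last registration before to the first after the silence). A
  single silent bird while others register is never excluded — a stationary
  bird is data, a dead reader is not.
* **Light period.** All activity is computed between 07:00 and 23:00
  (57,600 s); broilers are near-inactive in the dark and, on simulated
  data, the rank correlation between 24 h and light-period distances
  exceeds 0.9, so the light window is a faithful proxy.
* **Handling windows** (weighing, leg-band checks) are supplied through
  round metadata and excluded like gaps.
* **Effective duration.** Each bird-day carries
  `effective_seconds = 57,600 − excluded overlap`; distances are divided by
  effective hours so days with partial exclusions remain comparable. A day
  with zero effective time is missing, not an error.

## Kinematics

Birds are localised to the registering antenna's centre point; a 5 × 6
row-major grid in a 1.8 × 2.6 m pen puts neighbouring centres 0.36 m apart
within a row and 0.4333 m within a column. Daily distance is the sum of
straight-line centre-to-centre distances over consecutive registrations;
repeats on the same antenna contribute zero, and pairs straddling an
exclusion window contribute nothing (movement during unobserved intervals
is unknowable). No debouncing of rapid flicker between adjacent antennas is
applied: the raw registration stream is taken at face value, and a
sub-second duplicate at a switch is kept.

## Descriptors (per bird, ages ≤ 15 d)

Let x_d be the DADM on day d, observed on n days.

* **MD** = mean of the observed x_d (m/h). Requires ≥ 1 day.
* **Skew** = b₁ = m₃ / s³, where m₃ is the third central moment (divisor n)
  and s the (n−1)-denominator SD; equivalently g₁·((n−1)/n)^{3/2}. This is
  the default estimator of the R package `e1071`. Requires ≥ 3 days and
  non-zero variance.
* **RMSE**: fit an individual OLS line x_d ~ d (missing days simply
  absent; ≥ 3 days required), then RMSE = √[(1/n) Σ r_d²] over the
  residuals r_d. The divisor is n, not n−2, so with an OLS detrend
  absorbing two degrees of freedom, E[RMSE] ≈ σ·√((n−2)/n) ≈ 0.93 σ at
  n = 15 for deviations of SD σ. The recovery experiments test against
  this attenuated expectation.
* **AC** = Pearson correlation over pairs (r_d, r_{d+1}) restricted to
  *consecutive ages* where both days are observed (complete cases); ≥ 3
  pairs required. This deliberately differs from the full-series
  autocovariance estimator: pairs bridging a missing day would mix lags.
  Detrending short series biases AC downward (white noise gives ≈ −0.15 at
  15 days rather than 0); group orderings are preserved, which is what the
  recovery tests assert.
* **ENT**: per day, each light-period minute is flagged active when at
  least one registration lands on a different antenna than the immediately
  preceding one; active minutes are counted per 15-min bin (64 bins) and
  mapped to classes 1–4 with fixed cut-offs 0–2 / 3–4 / 5–7 / 8–15. Daily
  sample entropy SampEn(m = 2, r = 0.2·SD of the day's classes) is averaged
  over complete days only (entropy on a day with masked bins would not be
  comparable). Rounds with systemic registration problems can be excluded
  wholesale via `ent_exclude_rounds`.

**SampEn convention.** SampEn = −ln(A/B), where B counts unordered pairs of
distinct length-m templates within Chebyshev tolerance r and A the same for
length m+1, with templates of length L taken at starts 1..N−L. Under this
counting the strictly alternating 64-point series gives exactly
−ln(900/930) ≈ 0.0328. The convention differs from implementations that use
starts 1..N−m for both lengths in a single boundary template; on
non-degenerate 64-point class series the difference is below 0.05, and a
saturated (constant) series carries a small positive offset −ln(60/62)
rather than exactly zero. This finite-size offset is a known limitation,
irrelevant at the precision the descriptor is used.

**Outliers.** Descriptor values beyond 4 within-round SDs of the
within-round mean (mean and SD computed including the candidate, n−1
denominator) are set to missing cell-wise. ADG outliers under the same rule
remove the bird row-wise. Filtering order is fixed: scripted removals (sex
errors, deaths, birds removed from the pen) → ADG outliers (row-wise) →
descriptor outliers (cell-wise); the manifest records counts after each
stage.

## Growth and statistics

ADG = (end weight − start weight)/(end age − start age), g/day, over the
full round. Quartile groups pool rounds: low = ADG ≤ Q1, high = ADG ≥ Q3,
with quantiles by linear interpolation between order statistics and
inclusive ties (a degenerate all-tied cohort warns rather than errors).

Associations use Kendall's tau-b (tie-corrected; two-sided p from the
asymptotic normal approximation, z reported with the sign of tau) and a
percentile bootstrap CI over B = 1000 pair resamples (degenerate resamples
redrawn). Group contrasts use Wilcoxon rank-sum tests, exact when both
groups are ≤ 50 and untied, otherwise the tie-corrected normal
approximation (identical samples give p = 1 exactly). Each correlation
uses its own pairwise-complete pairs;
the linear model uses listwise-complete rows.

The ADG model starts from
`ADG ~ Round (sum-to-zero) + StartWeight + Skew + RMSE + AC + ENT`
— MD is excluded a priori because it is strongly rank-correlated with RMSE
and the two carry overlapping information — and is reduced in two stages:
backward removal of the term with the largest block F-test p > 0.05; then
all two-way interactions among the survivors are added and backward
selection repeats, never dropping a main effect while one of its
interactions remains (marginality). The fitted round effects over all
levels (including the implied last one) sum to zero by construction. The
reported F-table is sequential (Type I) in the fitted term order; users
comparing marginal tests should refit accordingly. A note on
interpretation: when a two-way interaction involving a continuous term
survives, the (uncentred) main-effect coefficient is a conditional slope,
which widens its sampling spread across simulation seeds; the recovery
experiment therefore evaluates the *mean* coefficient across seeds.

## The simulator

Per bird j the generator draws, from configurable priors: a linear
activity trend a_j + b_j·d (m/h; defaults a ~ N(24, 4²), b ~ N(−0.55,
0.15²), so activity declines with age), day-to-day deviations following a
stationary AR(1) with marginal SD σ_j (lognormal, mean ≈ 3.9 m/h) and lag-1
correlation ρ_j (truncated normal around 0.2), a within-day bout-regularity
knob reg_j ∈ [0, 1], a start weight W0_j ~ N(42, 3²) g, and
`ADG_true = β0 + β_SW·W0_j + β_RMSE·σ_j + noise`
(defaults 64.6 + 0.4·W0 − 1.0·σ + N(0, 10²) g/day, i.e. ADG ≈ 77 g/day
weakly and negatively coupled to activity variability). Daily targets are
truncated at zero, which mildly skews very low-activity birds.

Within a day, minutes alternate active/inactive bouts whose durations
interpolate between a fixed mean (reg = 1, rigidly periodic) and a
geometric law (reg = 0, memoryless), 5 min mean each. Movement is a
4-connected nearest-neighbour antenna walk at 1 Hz during active seconds.
The number of light-window hops is calibrated analytically: the stationary
expected step of a uniform nearest-neighbour walk equals the mean
undirected edge length of the grid (0.397 m on the 5 × 6 grid), so
`hops = target·16 h / mean step`, drawn as an exact count over the active
seconds (per-minute counts from the equivalent multivariate
hypergeometric). The registration round trip then recovers the target DADM
with a median relative error around 0.2% and ≥ 95% of days within 10% for
targets in 2–40 m/h. Outside the light window birds move at the same
per-second rate, damped ×0.05 during dark periods (23:00–03:00 and
05:00–07:00) — a configured default, not a fitted value.

Registration output has two modes: `full` (the true 1 Hz presence stream,
86,400 rows per bird-day) and the default `sparse` (one row per antenna
switch plus a once-per-minute heartbeat). Every downstream quantity —
distances, DADM, minute switch flags, effective durations, group-gap
detection — is invariant to dropping same-antenna repeats, so the two modes
are interchangeable for analysis while sparse keeps fixtures three orders
of magnitude smaller; the equivalence is asserted in the test suite.
Group-level outages arrive as a Poisson process and delete all birds'
registrations in the window; weekly weights lie on the bird's linear growth
line, rounded to 1 g at the start and 5 g later; RFID is generated up to
age 15 d by default (`rfid_max_age`) since no activity beyond that age
enters any descriptor.

What the simulator does *not* emulate: non-linear growth curves, density
dependence, mortality/culling dynamics, tag loss, antenna-specific
sensitivity (e.g. wet-bedding attenuation), or diurnal activity rhythms
beyond the light/dark contrast. Passing recovery tests therefore show that
the estimators recover the *assumed* generating structure, not that real
barn data satisfies those assumptions.

## Problem sizes and defaults

The default `SimConfig` mirrors a five-round experiment (80/82/82/78/80
male birds, start ages alternating 1/0 d, ends 33–36 d). Tests and the
acceptance script run reduced cohorts chosen to keep Monte-Carlo error
comfortably inside the asserted bands: 100–300 birds per group for
descriptor recovery, 50 seeds × 240 birds for effect recovery, 200 seeds
for type-I rates, 60 bird-days for the 1 Hz round trip, and pipeline runs
of 2–3 rounds × 8–20 birds.

## Known limitations

* AC from 15-day detrended series is biased downward; only orderings and
  group differences are interpretable, not absolute levels.
* The SampEn template-count convention has a small positive offset on
  perfectly regular series (see above).
* The bootstrap CI is percentile-based; no BCa correction.
* Backward stepwise selection inherits the usual post-selection inference
  caveats: reported p-values are conditional on the selected model.
* The quantile convention for ADG quartiles (linear interpolation) is one
  of several; group sizes can shift by a bird or two under other rules.
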