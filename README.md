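# locotrack

Early-life locomotor activity descriptors from RFID tracking — and their
relationship with body weight gain — for broiler chickens.

Fast-growing broilers are relatively inactive, and low activity is a major
contributor to leg weakness. Whether selecting for *more* early activity
would hurt growth is an open question for breeders and welfare scientists.
`locotrack` is a pipeline for answering it from passive-RFID floor-antenna
data: it turns second-resolution (timestamp, tag, antenna) registration
logs into per-bird **dynamic activity descriptors** over the first two
weeks of life and relates them to **average daily gain (ADG)** over the
production round. It is aimed at precision-livestock researchers working
with grid-antenna RFID systems, and at anyone who wants a fully testable
reference implementation of resilience-style activity descriptors.

## The descriptors

Each bird's daily average distance moved per hour (DADM, m/h; total
centre-to-centre antenna distance in the 07:00–23:00 light period divided
by the effectively recorded hours) over ages ≤ 15 d is reduced to:

| | Descriptor | Definition |
|---|---|---|
| MD | mean distance | mean of observed daily DADM (m/h) |
| Skew | skewness | b₁ = m₃/s³ of the daily values |
| RMSE | trend-residual RMSE | √[(1/n) Σ (x_obs − x_pred)²] around the bird's own OLS line DADM ~ age |
| AC | lag-1 autocorrelation | Pearson r over consecutive-age residual pairs (complete cases) |
| ENT | entropy | mean daily sample entropy, SampEn(m = 2, r = 0.2·SD), of 64 fifteen-minute activity classes (1–4) from minute-level antenna switches |

ADG = (weight_end − weight_start)/(age_end − age_start), g/day. The
statistical layer provides Kendall tau-b correlations with bootstrap 95%
CIs, Wilcoxon comparisons of the low/high ADG quartile groups, and a
backward-selected linear model `ADG ~ Round + StartWeight + RMSE + …`
under sum-to-zero contrasts. Cleaning follows group-level rules: sensor
silences > 5 min and handling periods are excluded, activity is clipped to
the light period, ADG outliers (> 4 within-round SD) remove the bird
row-wise, descriptor outliers are masked cell-wise.

Because raw farm registration data is rarely shareable, the package ships
a calibrated simulator (`locotrack.synthetic`): per-bird linear activity
trends with AR(1) day-to-day deviations, bout-structured within-day
movement of controllable regularity on a 5 × 6 antenna grid in a
1.8 × 2.6 m pen, sensor gaps, and weekly weights coupled (weakly,
negatively) to activity variability. Every stage of the pipeline is
validated by recovering these known generating parameters
(`locotrack.evaluation`).

## Worked example

```bash
locotrack run --out demo --seed 1
```

simulates the default five-round experiment (402 male birds, Table-style
round structure, ages 0/1 to 33–36 d), runs the full pipeline, and prints
the report. Abridged output from that exact command:

```
record counts: birds_at_start=402, with_growth_after_scripted_removals=402,
               after_adg_outlier_removal=402, descriptor_cells_masked=1, model_rows=321

Activity descriptors, mean (SD) per round
descriptor                           overall         round 1         round 2   ...
Mean distance (m/h)             19.53 (4.25)    19.38 (3.59)    18.78 (4.65)
Root mean square error           3.39 (1.61)     3.17 (1.35)     3.37 (1.86)
Entropy                          1.01 (0.13)              NA     1.00 (0.14)

Kendall rank correlations with ADG (bootstrap 95% CI)
descriptor                       tau              95% CI       z         P     n
Mean distance (m/h)           -0.051     [-0.116, 0.012]  -1.534    0.1250   402
Root mean square error        -0.120    [-0.178, -0.055]  -3.587    0.0003   401

Linear model of ADG (sum-to-zero contrasts, backward-selected)
final model: adg ~ rmse
n = 321, R^2 = 0.064, adjusted R^2 = 0.061
rmse  estimate -1.510  SE 0.324  t -4.663  P 0.0000
```

Reading it: entropy is NA in round 1 (that round is configured as
gap-ridden and excluded from ENT); of the five descriptors only the
trend-residual RMSE is associated with growth — birds whose activity
fluctuates more around their own declining trend gain ≈ 1.5 g/day less per
m/h of RMSE — while mean distance itself shows no significant link, and
the model explains only a few percent of ADG variance. That pattern is the
generating truth of the simulator (ADG is coupled to the deviation SD, not
to the activity level), recovered end-to-end from 1 Hz-equivalent
registration logs.

The same pipeline runs on real data laid out as the simulator writes it
(`locotrack simulate --out fixture/ …`): per-round RFID CSVs, a weight
table and a YAML round/roster file; see `locotrack run --input-dir`.

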