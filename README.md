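# frailgait

Preoperative frailty and adverse-outcome assessment from a pelvis-worn
smartphone accelerometer.

Older adults awaiting cardiac surgery are routinely screened with a 5-m
gait-speed test: walking slower than 0.833 m/s marks a patient as *frail*
and at elevated risk of postoperative morbidity and mortality. A phone worn
at the pelvis during that same 5-m walk and a 30-s quiet stance yields far
more than a stopwatch time: tri-axial acceleration captures gait speed,
inter-step timing, movement variability (per-axis RMS), and the temporal
*complexity* of postural sway (approximate entropy). `frailgait` implements
that full assessment for biomechanics and perioperative-research groups:
signal processing, feature extraction, frailty classification, a published
linear risk score, model refitting with diagnostics, and cut-point
analysis — plus a seeded synthetic-data generator so the whole pipeline is
testable without any clinical recordings.

## What it computes

**Gait features** from the 5-m walk (50 Hz tri-axial acceleration in g,
axes AP / ML / V):

- zero-phase 4th-order Butterworth low-pass at 6 Hz;
- walk boundaries from the half-second moving-window variance of the
  resultant acceleration, thresholded against the initial stand-still
  baseline; average velocity `v = 5 m / (t_stop − t_start)`;
- inter-step times from vertical-axis peak events;
- RMS_AP, RMS_V, RMS_ML of the mean-removed walking accelerations.

**Posture features** from the 30-s stance, on a planar sway proxy
(mean-removed AP/ML acceleration scaled to mm):

- approximate entropy

  `ApEn(N, m, d) = Φ^m(d) − Φ^{m+1}(d)`,
  `Φ^k(d) = (N−k+1)^{-1} Σ_i ln C_i^k(d)`,

  with pattern length `m = 2`, Chebyshev tolerance `d = 0.2 × SD`, and
  self-matches included — low ApEn means regular, predictable sway;
- sway path length, mean sway velocity, mean sway radius, 95%-confidence-
  ellipse sway area, and sway SD.

**Clinical outputs**:

- frailty label (`frail` iff speed < 0.833 m/s; a 0.65 m/s severe threshold
  is also provided);
- the published adverse-outcome score

  `Score = 44.13 − 26.96·RMS_AP − 28.29·RMS_V + 13.33·ApEn_ML
  − 46.85·ApEn_R + 5.35·StepTime`;

- severity-weighted outcome scoring (death 7, prolonged ventilation 6,
  prolonged stay 5, SNF discharge 4, stroke/renal failure 3, reoperation 2,
  deep sternal wound infection 1);
- OLS refitting with R², Mallows' Cp and VIF diagnostics, two-group
  comparisons, and exhaustive sensitivity/specificity cut-point scans.

## Worked example

Simulate a seeded 8-subject cohort and assess the first (frail) subject:

```sh
frailgait simulate --n 8 --frail-fraction 0.5 --seed 7 --out-dir demo
frailgait report --stance demo/stance_S001.csv --walk demo/walk_S001.csv --subject-id S001
```

```text
Subject S001 (config a5d4bc1b5441)
  gait speed       : 0.672 m/s -> frail
  mean step time   : 0.698 s (10 steps)
  RMS AP/V/ML      : 0.104 / 0.100 / 0.100 g
  ApEn ML/AP/V/R   : 0.642 / 0.647 / 0.776 / 0.852
  sway SD / radius : 4.833 / 11.561 mm
  sway path / vel  : 3506.187 mm / 116.951 mm/s
  adverse score    : 10.897
  cut-off smartphone_velocity<=0.716: POSITIVE
  cut-off rms_v<=0.137: POSITIVE
  cut-off step_time>0.533: POSITIVE
  cut-off apen_r_cop<=1.139: POSITIVE
```

The subject walks 5 m at 0.672 m/s — below the 0.833 m/s threshold, hence
frail — with long (0.698 s) steps and low movement amplitude (RMS ≈ 0.10 g,
at the frail end of the 0.11–0.17 g clinical range). All four published
single-variable morbidity cut-offs fire. Refitting the score model on the
simulated cohort recovers strong fit diagnostics and no multicollinearity:

```sh
frailgait fit --features demo/features.csv --outcomes demo/outcomes.csv
```

```text
intercept = 1.243
rms_ap: -44.987 (VIF 2.10)
...
R^2 = 0.955, Cp = 6.000, VIF flag = False
```

The same things are available as a library:

```python
from frailgait import AdverseScoreModel

model = AdverseScoreModel.published()
model.predict({"rms_ap": 0.093, "rms_v": 0.118, "apen_ml_cop": 0.991,
               "apen_r_cop": 1.105, "step_time": 0.550})
# 2.6678  — a low-risk patient (scores >= ~4 accompanied adverse outcomes)
```

## Layout

| module | contents |
| --- | --- |
| `frailgait.trace` | `AccelerationTrace` container + delimited-text I/O |
| `frailgait.synthetic` | seeded walk/stance/cohort generators |
| `frailgait.gait` | filtering, walk detection, speed, steps, RMS |
| `frailgait.posture` | approximate entropy, sway proxy, sway metrics |
| `frailgait.outcomes` | frailty, outcome scores, score model, fits, cut-points |
| `frailgait.pipeline` | config, orchestration, assessment reports |
| `frailgait.cli` | `frailgait simulate/extract/score/fit/cutpoints/report` |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
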