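# Methods

This note records the models, parameter choices and assumptions behind
`frailgait`, including the decisions taken where the clinical protocol the
package implements leaves the procedure open.

## Signal chain

All accelerations are kept in units of g end-to-end; traces carry a uniform
time base (jitter tolerance 1e-6 s) with axis order AP, ML, V declared in
the file header (`time_s,acc_ap_g,acc_ml_g,acc_v_g`).

**Filtering.** A 4th-order low-pass Butterworth at 6 Hz, applied forward and
backward (`scipy.signal.sosfiltfilt`) for zero net phase. The effective
magnitude response is the squared single-pass response, so a sinusoid at
twice the cut-off is attenuated by ≈48 dB. Gait and sway content live below
~5 Hz at clinical walking speeds, so the pass band preserves everything of
interest.

**Walk detection.** The detector computes the unbiased sample variance of
the mean-removed resultant acceleration in dense half-second windows
(hop = 1 sample) and thresholds it at `multiplier × baseline` (default 3×),
where the baseline is the maximum window variance over the initial
stand-still. Two choices deserve note:

- *Calibration margins.* Half a second is discarded at both ends of the
  quiet prefix: the head for filter start-up transients, and the tail
  because zero-phase filtering is non-causal and smears walking energy
  backward into the quiet period — without the tail margin the baseline is
  inflated roughly tenfold and the detected walk end drifts early. The
  usable prefix must still cover ≥4 windows, so ≥2.5 s of quiet stance is
  required before the walk (the generator emits 3 s).
- *Boundary labelling.* Only supra-threshold runs sustained for ≥0.5 s count
  as walking. Boundaries are labelled by the window edge adjacent to the
  quiet side (trailing edge of the first active window, leading edge of the
  last). Labelling by window *centers* would bias each boundary outward by
  up to half a window (0.25 s) whenever walking variance dwarfs the stance
  baseline — the usual case — whereas edge labelling is accurate to a few
  samples. On the synthetic cohort the worst boundary error observed is
  ~0.12 s.

**Gait speed** is walkway length over detected walk duration; the default
walkway is 5 m. **Step events** are peaks of the filtered, mean-removed
vertical axis with a 0.25 s refractory period and prominence ≥0.5 segment
SDs; the inter-step times are successive peak intervals. The clinical
protocol reports inter-step time without defining its extraction, so this
peak-picking rule is a package design choice. **RMS** is computed per axis
on mean-removed walking-segment signal — retaining the +1 g gravity
component on V would make RMS_V ≈ 1 g, an order of magnitude above the
0.11–0.17 g clinical range, so mean removal is the only reading consistent
with those magnitudes.

## Approximate entropy

`ApEn(N, m, d) = Φ^m(d) − Φ^{m+1}(d)` with
`Φ^k(d) = (N−k+1)^{-1} Σ_i ln C_i^k(d)`, where `C_i^k(d)` is the fraction
of length-`k` embedded vectors within Chebyshev distance `d` of vector `i`,
self-matches included. Defaults: `m = 2`, `d = 0.2 × SD` of the series.
Choices:

- *Tolerance.* The tolerance is expressed as a fraction of the series SD
  (default 0.2, the standard choice with reasonable statistical validity),
  which makes ApEn exactly invariant under affine rescaling. A tolerance of
  0.002 × SD would saturate ApEn toward its maximum on essentially every
  physiological signal.
- *Self-matches* keep every count positive, so no `ln 0` can occur.
- *Degenerate input.* A constant series returns 0 with a warning (perfectly
  regular).
- *Range.* ApEn is not clamped. It is non-negative for realistic series,
  but because `Φ^m` and `Φ^{m+1}` average over different numbers of
  templates, marginally negative values can occur for very short, highly
  structured series; the test suite demonstrates one such 8-sample case on
  which the production implementation and a naive double-loop oracle agree
  to 1e-12. Claims that ApEn lives in [0, 2] hold only for typical signals
  and tolerances and are not asserted.

**Sway proxy.** How a waist-worn phone yields a center-of-pressure series is
not defined by the protocol; the package uses mean-removed planar (AP, ML)
acceleration scaled by 1000 mm/g as a displacement-like proxy, and tags
every output with `acceleration-proxy` so downstream users cannot mistake
it for force-plate COP. ApEn values computed on this filtered proxy run
lower than force-plate-era reference values (~1.1); comparisons should stay
within one derivation. Dispersion metrics follow standard posturography:
path length (sum of planar displacements), mean velocity (path/duration),
mean radius (mean distance from centroid), sway area (95% confidence
ellipse, chi-square 2 df), and sway SD (SD of the resultant radius).

## Clinical models

**Frailty** is gait speed < 0.833 m/s, strictly: a subject at exactly the
threshold is non-frail. A 0.65 m/s severe threshold is exposed as a
constant.

**Outcome score.** Events are weighted death = 7, prolonged ventilation = 6,
prolonged stay = 5, SNF discharge = 4, stroke = renal failure = 3,
reoperation = 2, DSWI = 1, and combined by `sum` (default) or `max`. `sum`
is the default because multi-event patients plausibly carry a composite
burden above the single-event ceiling; the aggregation is configurable
because the combination rule is not fixed by the protocol.

**Adverse-outcome model.** The published instance stores the printed
two-decimal coefficients exactly (intercept 44.13; −26.96, −28.29, +13.33,
−46.85, +5.35 on RMS_AP, RMS_V, ApEn_ML, ApEn_R, StepTime). Worked-example
evaluations therefore carry up to ±0.06 of rounding slack. Refitting is
plain OLS (statsmodels); diagnostics are R², Mallows' Cp referenced to the
full five-predictor model (for which Cp equals the parameter count, 6, by
construction), and per-predictor VIF with a flag at VIF ≥ 5. A rank-
deficient design raises a singular-design error carrying the VIFs (infinite
for perfectly collinear columns). Group comparisons default to Welch's
t-test with a Mann–Whitney option, since the protocol reports p-values
without naming a test.

**Cut-points.** The scan is exhaustive over midpoints between consecutive
sorted unique values; the winner maximizes sensitivity + specificity with
ties broken toward higher sensitivity, then toward the lower threshold.
Morbidity for cut-point purposes is outcome score ≥ 1.

## Synthetic data

The generator emulates the study conditions: 50 Hz sampling, a 3 s quiet
lead, a 5 m walk, a 30 s stance, white sensor noise of 0.01 g SD, and a
half-frail 16-subject cohort.

**Walk signal.** Per axis, a sum of harmonics at the step frequency
(vertical: fundamental + 0.3× second harmonic; AP: fundamental + 0.25×;
ML: stride frequency = half the step frequency), amplitudes solved in
closed form so the deterministic component hits the per-axis RMS target,
plus gravity (+1 g on V) and sensor noise. Frail defaults: speed 0.67 m/s,
step time 0.654 s, RMS targets (0.12, 0.11, 0.11) g; non-frail: 0.98 m/s,
0.573 s, (0.15, 0.17, 0.15) g — the group means of the clinical cohort. A
walk shorter than 4 step cycles is rejected as unusable.

**Stance signal.** Planar channels are the convex mixture
`reg × periodic + (1 − reg) × noise` (components normalized to unit RMS
before mixing, then scaled to 0.01 g per axis), with slow sinusoids at
0.40/0.55 Hz as the periodic part and 12 Hz-low-passed white noise as the
irregular part. `reg = 1` yields ApEn ≈ 0.24 on the raw ML channel;
`reg = 0` yields ≈ 1.4; means over seeds are monotone in between. With the
1000 mm/g proxy scale, the resulting sway SD sits at a few mm, the order of
the clinical frailty cut-off (6.45 mm).

**Cohorts.** Feature rows are drawn directly from group-conditional normal
distributions anchored to the clinical cohort moments (normality is a
generator assumption; the cohort tables only constrain means and SDs). The
latent adverse score is the published model evaluated at the drawn features
plus N(0, `score_noise_sd`²) noise (default SD 0.5 score units; 0 gives an
exactly linear cohort on which OLS recovers the published coefficients to
machine precision). Discrete events are thresholds on the latent score
(SNF 3.9, prolonged ventilation 4.4, stroke 4.7, renal failure 5.4,
reoperation 5.6, prolonged stay 5.8, death 6.1, DSWI 7.0), chosen once so
that a 16-subject half-frail cohort shows roughly the clinical prevalence
pattern (≈4 SNF, 3 prolonged ventilation, 2 strokes, ~1 each of the rarer
events, DSWI rare).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanical gait dynamics (no double support,
asymmetry, turning, or sit-to-stand kinematics), phone orientation drift
and soft-tissue artifact, non-stationary sway, non-normal feature
distributions, and any real coupling between gait features and outcomes
beyond the assumed linear-score mechanism. Recovery results on synthetic
data validate the *implementation*, not the clinical validity of the
features.

## Problem sizes and tolerances

Cohort-level checks use 50 seeded subjects per group for gait recovery
(mean speed and step time within 5% of truth, walk bounds within ±0.2 s),
20 seeds for entropy-regularity checks, and 100 random series (N ≤ 200,
m ∈ {1, 2, 3}) for oracle equivalence at 1e-12 — sizes at which the full
suite runs in seconds while estimator variance is far below the asserted
bands. Reports print at 3 decimals; machine-readable outputs keep full
precision. Determinism is a contract: every random draw flows from one
seeded `numpy` generator per call, and identical (inputs, config, seed)
reproduce byte-identical reports.

## Known limitations

- The acceleration sway proxy is not a validated COP surrogate; ApEn and
  dispersion values are internally consistent but not comparable to
  force-plate numbers.
- The published model is stored at printed precision; scores inherit that
  rounding.
- Walk detection assumes a single walking bout bounded by quiet periods;
  recordings with movement artifacts before the walk will bias the
  boundaries, as the underlying protocol itself cautions.
- Step detection assumes a dominant vertical periodicity; severely ataxic
  gait may defeat the fixed refractory/prominence rule.
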