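"""Seeded synthetic accelerometry and cohorts for the assessment pipeline.

No raw patient recordings are publicly available for this protocol, so this
module emulates them: a pelvis-worn phone sampling at 50 Hz through a quiet
stand-still, a 30-s quiet stance, and a 5-m walk, with frail / non-frail
group structure calibrated to the published cohort moments (frail gait speed
around 0.67 m/s vs 0.98 m/s non-frail, step times around 0.654 vs 0.573 s,
walking RMS levels of 0.11-0.17 g).

The walking signal is a sum of harmonics at the step frequency (vertical
dominant, anterior-posterior second, medial-lateral at the stride frequency)
with amplitudes solved analytically to hit the per-axis RMS targets, plus
white sensor noise; gravity appears as a constant +1 g offset on the
vertical axis. The quiet-stance sway signal is a convex mixture of a slow
periodic component and band-limited noise controlled by ``sway_regularity``:
1 means purely periodic (low approximate entropy), 0 means pure noise (high
approximate entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidParameterError, UnusableTrialError
from .outcomes import EVENT_NAMES, SEVERITY_WEIGHTS, AdverseScoreModel
from .trace import AccelerationTrace, make_time

#: quiet lead before the walk and trailing quiet after it, seconds
WALK_LEAD_S = 3.0
WALK_TRAIL_S = 2.0

#: second-harmonic amplitude ratios of the walking signal
_HARMONIC_V = 0.3
_HARMONIC_AP = 0.25

#: stance sway-proxy RMS per planar axis, g
STANCE_AMPLITUDE_G = 0.01
#: cut-off of the band-limited stance noise component, Hz
STANCE_NOISE_CUTOFF_HZ = 12.0

#: group-conditional feature moments (mean, sd) used by the cohort generator,
#: anchored to the published morbid / non-morbid cohort statistics
FRAIL_MOMENTS: dict[str, tuple[float, float]] = {
    "smartphone_velocity": (0.67, 0.064),
    "rms_ap": (0.113, 0.033),
    "rms_v": (0.114, 0.016),
    "apen_ml_cop": (1.101, 0.018),
    "apen_r_cop": (1.113, 0.021),
    "step_time": (0.654, 0.150),
}
NONFRAIL_MOMENTS: dict[str, tuple[float, float]] = {
    "smartphone_velocity": (0.98, 0.150),
    "rms_ap": (0.128, 0.026),
    "rms_v": (0.136, 0.034),
    "apen_ml_cop": (1.077, 0.068),
    "apen_r_cop": (1.141, 0.033),
    "step_time": (0.573, 0.081),
}

#: feature truncation bounds keeping draws physically plausible
_FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "smartphone_velocity": (0.2, 2.0),
    "rms_ap": (0.02, 0.4),
    "rms_v": (0.02, 0.4),
    "apen_ml_cop": (0.5, 2.0),
    "apen_r_cop": (0.5, 2.0),
    "step_time": (0.3, 1.2),
}

#: latent-score thresholds mapping the adverse score to discrete events;
#: chosen once so that event prevalence in a 16-subject half-frail cohort
#: roughly matches the published cohort (4 SNF, 3 prolonged ventilation,
#: 2 strokes, 1 each renal failure / reoperation / long stay / death, 0 DSWI)
EVENT_THRESHOLDS: dict[str, float] = {
    "snf_discharge": 3.9,
    "prolonged_ventilation": 4.4,
    "stroke": 4.7,
    "renal_failure": 5.4,
    "reoperation": 5.6,
    "prolonged_stay": 5.8,
    "death": 6.1,
    "dswi": 7.0,
}


@dataclass
class SubjectProfile:
    """Ground-truth parameters for one simulated subject."""

    group: str  # "frail" | "non-frail"
    true_gait_speed: float  # m/s
    true_step_time: float  # s
    rms_targets: tuple[float, float, float]  # (AP, V, ML), g
    sway_regularity: float  # in [0, 1]
    outcome_events: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.group not in ("frail", "non-frail"):
            raise InvalidParameterError("group must be 'frail' or 'non-frail'")
        if self.true_gait_speed <= 0 or self.true_step_time <= 0:
            raise InvalidParameterError("speed and step time must be positive")
        if any(r <= 0 for r in self.rms_targets):
            raise InvalidParameterError("rms_targets must all be positive")
        if not (0 <= self.sway_regularity <= 1):
            raise InvalidParameterError("sway_regularity must lie in [0, 1]")
        unknown = set(self.outcome_events) - set(EVENT_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown outcome events: {sorted(unknown)}")

    @classmethod
    def frail(cls) -> "SubjectProfile":
        return cls(
            group="frail",
            true_gait_speed=0.67,
            true_step_time=0.654,
            rms_targets=(0.12, 0.11, 0.11),
            sway_regularity=0.6,
        )

    @classmethod
    def non_frail(cls) -> "SubjectProfile":
        return cls(
            group="non-frail",
            true_gait_speed=0.98,
            true_step_time=0.573,
            rms_targets=(0.15, 0.17, 0.15),
            sway_regularity=0.4,
        )


@dataclass
class CohortConfig:
    """Study-condition parameters shared by all generators."""

    n_subjects: int = 16
    frail_fraction: float = 0.5
    sampling_rate: float = 50.0  # Hz
    stance_duration: float = 30.0  # s
    walk_distance: float = 5.0  # m
    noise_sd: float = 0.01  # g, white sensor noise
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if not (0 <= self.frail_fraction <= 1):
            raise InvalidParameterError("frail_fraction must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.walk_distance <= 0:
            raise InvalidParameterError("walk_distance must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def generate_walk_trace(
    profile: SubjectProfile, config: CohortConfig, seed: int
) -> tuple[AccelerationTrace, dict]:
    """Simulate a stand-still + 5-m-walk recording with ground truth.

    The trace starts with ``WALK_LEAD_S`` seconds of quiet standing (gravity
    baseline plus sensor noise), followed by a walking bout lasting
    ``walk_distance / true_gait_speed`` seconds whose dominant vertical
    periodicity is the step frequency ``1 / true_step_time`` and whose
    per-axis RMS matches ``rms_targets``, then a short trailing quiet tail.

    Returns the trace and a ground-truth dict with keys ``walk_start_s``,
    ``walk_stop_s``, ``speed`` and ``step_times``.
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(seed)
    walk_duration = config.walk_distance / profile.true_gait_speed
    n_cycles = walk_duration / profile.true_step_time
    if n_cycles < 4:
        raise UnusableTrialError(
            f"walk of {walk_duration:.2f} s covers only {n_cycles:.1f} step "
            "cycles (< 4); trial unusable"
        )
    n_lead = int(round(WALK_LEAD_S * fs))
    n_walk = int(round(walk_duration * fs))
    n_trail = int(round(WALK_TRAIL_S * fs))
    n = n_lead + n_walk + n_trail
    time = make_time(n, fs)

    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0  # gravity on the vertical axis, in g
    acc += rng.normal(0.0, config.noise_sd, size=(n, 3))

    tw = (np.arange(n_walk) / fs)
    f_step = 1.0 / profile.true_step_time
    phase = rng.uniform(0, 2 * np.pi)
    rms_ap, rms_v, rms_ml = profile.rms_targets

    # amplitudes solved so the deterministic component hits the RMS target:
    # RMS of a + h-harmonic pair = a * sqrt((1 + h^2) / 2)
    a_v = rms_v / np.sqrt((1 + _HARMONIC_V**2) / 2)
    a_ap = rms_ap / np.sqrt((1 + _HARMONIC_AP**2) / 2)
    a_ml = rms_ml * np.sqrt(2)

    sl = slice(n_lead, n_lead + n_walk)
    acc[sl, 2] += a_v * (
        np.sin(2 * np.pi * f_step * tw + phase)
        + _HARMONIC_V * np.sin(4 * np.pi * f_step * tw + 2 * phase + 0.7)
    )
    acc[sl, 0] += a_ap * (
        np.sin(2 * np.pi * f_step * tw + phase + 1.1)
        + _HARMONIC_AP * np.sin(4 * np.pi * f_step * tw + 2 * phase + 1.9)
    )
    acc[sl, 1] += a_ml * np.sin(np.pi * f_step * tw + phase + 0.5)  # stride frequency

    trace = AccelerationTrace(time, acc, fs)
    n_steps = int(np.floor(n_cycles))
    ground_truth = {
        "walk_start_s": n_lead / fs,
        "walk_stop_s": (n_lead + n_walk) / fs,
        "speed": profile.true_gait_speed,
        "step_times": [profile.true_step_time] * max(0, n_steps - 1),
    }
    return trace, ground_truth


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if cutoff >= fs / 2:
        return white
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt((x**2).mean())
    return x / r if r > 0 else x


def generate_stance_trace(
    profile: SubjectProfile, config: CohortConfig, seed: int
) -> tuple[AccelerationTrace, np.ndarray]:
    """Simulate a quiet-stance recording with a regularity-controlled sway.

    The planar (AP, ML) channels are the convex mixture
    ``sway_regularity * periodic + (1 - sway_regularity) * band-limited
    noise`` with each component normalized to unit RMS before mixing, scaled
    to ``STANCE_AMPLITUDE_G``; more regular mixtures yield lower approximate
    entropy. The vertical channel is gravity plus sensor noise.

    Returns the trace and the ground-truth planar sway series, shape (n, 2).
    """
    if config.stance_duration < 5:
        raise InvalidParameterError("stance_duration must be >= 5 s")
    fs = config.sampling_rate
    rng = np.random.default_rng(seed)
    n = int(round(config.stance_duration * fs))
    t = make_time(n, fs)
    reg = profile.sway_regularity

    planar = np.empty((n, 2))
    for k, f_sway in enumerate((0.40, 0.55)):  # AP, ML sway frequencies, Hz
        phase = rng.uniform(0, 2 * np.pi)
        periodic = _unit_rms(np.sin(2 * np.pi * f_sway * t + phase))
        noise = _unit_rms(_bandlimited_noise(rng, n, fs, STANCE_NOISE_CUTOFF_HZ))
        mix = reg * periodic + (1 - reg) * noise
        planar[:, k] = STANCE_AMPLITUDE_G * _unit_rms(mix)

    acc = np.zeros((n, 3))
    acc[:, 0] = planar[:, 0]
    acc[:, 1] = planar[:, 1]
    acc[:, 2] = 1.0 + rng.normal(0.0, config.noise_sd, size=n)
    return AccelerationTrace(t, acc, fs), planar


def _draw_feature(rng: np.random.Generator, name: str, moments: dict) -> float:
    mean, sd = moments[name]
    lo, hi = _FEATURE_BOUNDS[name]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def draw_profile(group: str, config: CohortConfig, rng: np.random.Generator) -> SubjectProfile:
    """Randomize a subject profile around the group-typical parameters."""
    moments = FRAIL_MOMENTS if group == "frail" else NONFRAIL_MOMENTS
    base = SubjectProfile.frail() if group == "frail" else SubjectProfile.non_frail()
    speed = _draw_feature(rng, "smartphone_velocity", moments)
    step = _draw_feature(rng, "step_time", moments)
    rms_ap = _draw_feature(rng, "rms_ap", moments)
    rms_v = _draw_feature(rng, "rms_v", moments)
    rms_ml = float(np.clip(rng.normal(*(  # ML from the walk-RMS table rows
        (0.11, 0.02) if group == "frail" else (0.15, 0.03))), 0.02, 0.4))
    reg = float(np.clip(rng.normal(base.sway_regularity, 0.05), 0.0, 1.0))
    return SubjectProfile(
        group=group,
        true_gait_speed=speed,
        true_step_time=step,
        rms_targets=(rms_ap, rms_v, rms_ml),
        sway_regularity=reg,
    )


def generate_cohort(
    config: CohortConfig, score_noise_sd: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort feature table and matching outcome table.

    Each subject's five model predictors (plus smartphone velocity) are drawn
    from group-conditional normal distributions calibrated to the published
    cohort moments; a latent adverse score is the published linear model
    evaluated at the features plus zero-mean Gaussian noise with SD
    ``score_noise_sd`` (0 makes the latent score exactly the model
    prediction); discrete postoperative events are thresholds on the latent
    score, and the severity-weighted outcome score is their sum.
    """
    if config.n_subjects < 2:
        raise InvalidParameterError("need at least 2 subjects to form groups")
    if score_noise_sd < 0:
        raise InvalidParameterError("score_noise_sd must be >= 0")
    rng = np.random.default_rng(config.seed)
    model = AdverseScoreModel.published()
    n_frail = int(round(config.frail_fraction * config.n_subjects))
    groups = ["frail"] * n_frail + ["non-frail"] * (config.n_subjects - n_frail)

    feat_rows, out_rows = [], []
    for i, group in enumerate(groups):
        moments = FRAIL_MOMENTS if group == "frail" else NONFRAIL_MOMENTS
        row = {name: _draw_feature(rng, name, moments) for name in moments}
        latent = model.predict(row)
        if score_noise_sd > 0:
            latent += rng.normal(0.0, score_noise_sd)
        events = {name: bool(latent >= EVENT_THRESHOLDS[name]) for name in EVENT_NAMES}
        score = sum(SEVERITY_WEIGHTS[name] for name, hit in events.items() if hit)
        subject_id = f"S{i + 1:03d}"
        feat_rows.append({"subject_id": subject_id, "group": group, **row})
        out_rows.append(
            {"subject_id": subject_id, **events, "outcome_score": score, "latent_score": latent}
        )
    features = pd.DataFrame(feat_rows)
    outcomes = pd.DataFrame(out_rows)
    return features, outcomes
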