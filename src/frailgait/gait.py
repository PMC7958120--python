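"""Gait features from a pelvis-worn accelerometer.

The processing chain mirrors the clinical 5-m walk protocol: zero-phase
low-pass filtering, resultant acceleration, stand-still-calibrated walk
detection via half-second moving-window variance, average gait speed over a
known distance, step events from the vertical axis, and per-axis RMS of the
mean-removed walking accelerations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import (
    CalibrationError,
    InvalidParameterError,
    NoWalkDetectedError,
    TooFewStepsError,
)
from .trace import AccelerationTrace

#: seconds excluded at each end of a filtered trace when estimating the
#: stand-still baseline, to avoid filter edge transients
EDGE_MARGIN_S = 0.5


@dataclass(frozen=True)
class StandstillCalibration:
    """Movement-detection threshold derived from the initial stand-still.

    ``baseline_variance`` is the largest half-second moving-window variance of
    the mean-removed resultant acceleration over the quiet prefix;
    ``threshold`` is ``multiplier`` times that baseline.
    """

    baseline_variance: float  # g^2
    threshold: float  # g^2

    def __post_init__(self):
        if not (self.threshold >= self.baseline_variance > 0):
            raise InvalidParameterError("require threshold >= baseline_variance > 0")


@dataclass(frozen=True)
class WalkSegment:
    """Detected walking interval with the instrumented walkway length."""

    start_time: float
    stop_time: float
    distance: float = 5.0

    def __post_init__(self):
        if self.stop_time <= self.start_time:
            raise InvalidParameterError("stop_time must exceed start_time")
        if self.distance <= 0:
            raise InvalidParameterError("distance must be positive")

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time


@dataclass
class GaitFeatures:
    velocity: float  # m/s
    step_times: list[float]  # s
    mean_step_time: float  # s
    rms_ap: float  # g
    rms_v: float  # g
    rms_ml: float  # g


def lowpass_filter(trace: AccelerationTrace, cutoff: float = 6.0, order: int = 4) -> AccelerationTrace:
    """Zero-phase per-axis Butterworth low-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``) so the net
    phase shift is zero; the effective magnitude response is the squared
    single-pass Butterworth response.

    Parameters
    ----------
    cutoff : float
        Cut-off frequency in Hz; must be below the Nyquist frequency.
    order : int
        Order of the underlying (single-pass) Butterworth design.
    """
    nyquist = trace.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below Nyquist ({nyquist} Hz)"
        )
    if cutoff <= 0 or order < 1:
        raise InvalidParameterError("cutoff must be > 0 and order >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    filtered = np.column_stack([sps.sosfiltfilt(sos, trace.acc[:, k]) for k in range(3)])
    return trace.replace_acc(filtered)


def resultant_acceleration(trace: AccelerationTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration axes, in g."""
    return np.linalg.norm(trace.acc, axis=1)


def moving_window_variance(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Dense (hop = 1 sample) unbiased sample variance over sliding windows.

    Returns one value per window position ``i`` covering samples
    ``x[i : i + window_samples]``.
    """
    if window_samples < 2:
        raise InvalidParameterError("window must span at least 2 samples")
    if x.size < window_samples:
        raise InvalidParameterError("signal shorter than one window")
    return sliding_window_view(x, window_samples).var(axis=1, ddof=1)


def _window_samples(window: float, fs: float) -> int:
    w = int(round(window * fs))
    if w < 2:
        raise InvalidParameterError(f"window {window} s too short at {fs} Hz")
    return w


def calibrate_standstill(
    trace: AccelerationTrace,
    window: float = 0.5,
    multiplier: float = 3.0,
    standstill_duration: float = 3.0,
) -> StandstillCalibration:
    """Derive the movement threshold from the initial stand-still.

    The first ``standstill_duration`` seconds of the (already filtered) trace
    are taken as quiet; ``EDGE_MARGIN_S`` seconds are discarded at both ends
    of that prefix — the head to avoid filter start-up transients, the tail
    because zero-phase filtering is non-causal and smears movement energy
    backward into the quiet period. The baseline is the maximum moving-window
    variance of the mean-removed resultant over the remaining prefix, and the
    threshold is ``multiplier`` times that.
    """
    if multiplier < 1:
        raise InvalidParameterError("multiplier must be >= 1")
    fs = trace.sampling_rate
    w = _window_samples(window, fs)
    r = resultant_acceleration(trace)
    r = r - r.mean()
    start = int(round(EDGE_MARGIN_S * fs))
    stop = int(round((standstill_duration - EDGE_MARGIN_S) * fs))
    prefix = r[start:stop]
    if prefix.size < 4 * w:
        raise CalibrationError(
            "stand-still prefix shorter than 4 windows after the edge margins; "
            "record at least "
            f"{2 * EDGE_MARGIN_S + 4 * window:.1f} s of quiet stance before walking"
        )
    baseline = float(moving_window_variance(prefix, w).max())
    if baseline <= 0:
        raise CalibrationError(
            "stand-still prefix has zero variance (synthetic noiseless input?); "
            "a real accelerometer always carries sensor noise — add noise or "
            "supply an explicit threshold"
        )
    return StandstillCalibration(baseline_variance=baseline, threshold=multiplier * baseline)


def detect_walk_bounds(
    trace: AccelerationTrace,
    calib: StandstillCalibration,
    window: float = 0.5,
    distance: float = 5.0,
    min_sustained: float = 0.5,
) -> WalkSegment:
    """Locate the walking bout via thresholded moving-window variance.

    A window position is *active* when its variance exceeds the calibrated
    threshold; only runs of active positions sustained for at least
    ``min_sustained`` seconds count as walking. The walk start is the time of
    the trailing (newest-sample) edge of the first active window and the stop
    is the leading edge of the last active window, so each boundary is
    labelled by the window edge adjacent to the quiet side and is accurate to
    a few samples rather than biased by half a window.
    """
    fs = trace.sampling_rate
    w = _window_samples(window, fs)
    r = resultant_acceleration(trace)
    var = moving_window_variance(r - r.mean(), w)
    active = var > calib.threshold
    if not active.any():
        raise NoWalkDetectedError("no walk detected: no window exceeds the threshold")
    min_run = max(1, int(round(min_sustained * fs)))
    runs = _runs(active)
    runs = [(a, b) for a, b in runs if b - a >= min_run]
    if not runs:
        raise NoWalkDetectedError(
            "no walk detected: no supra-threshold run sustained for "
            f"{min_sustained} s"
        )
    first_start = runs[0][0]
    last_end = runs[-1][1] - 1  # inclusive index of last active window position
    start_time = float(trace.time[first_start + w - 1])
    stop_time = float(trace.time[last_end])
    if stop_time - start_time < 1.0:
        warnings.warn(
            f"implausible walk: detected bout lasts {stop_time - start_time:.2f} s",
            RuntimeWarning,
            stacklevel=2,
        )
    return WalkSegment(start_time=start_time, stop_time=stop_time, distance=distance)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def gait_speed(segment: WalkSegment) -> float:
    """Average walking velocity over the instrumented distance, m/s."""
    return segment.distance / segment.duration


def detect_steps(
    trace: AccelerationTrace,
    segment: WalkSegment,
    refractory: float = 0.25,
    prominence_sd: float = 0.5,
) -> tuple[list[float], float]:
    """Step events as vertical-axis peaks inside the walking segment.

    Peaks of the mean-removed (filtered) vertical acceleration must be
    separated by at least ``refractory`` seconds and have prominence of at
    least ``prominence_sd`` standard deviations of the segment signal.
    Returns the successive inter-peak intervals and their mean.
    """
    fs = trace.sampling_rate
    sel = (trace.time >= segment.start_time) & (trace.time <= segment.stop_time)
    v = trace.v[sel]
    t = trace.time[sel]
    if v.size < 2:
        raise TooFewStepsError("walking segment contains no samples")
    v = v - v.mean()
    sd = v.std(ddof=0)
    peaks, _ = sps.find_peaks(
        v,
        distance=max(1, int(round(refractory * fs))),
        prominence=prominence_sd * sd if sd > 0 else None,
    )
    if peaks.size < 3:
        raise TooFewStepsError(
            f"too few steps: {peaks.size} events detected, need at least 3"
        )
    step_times = np.diff(t[peaks])
    return [float(s) for s in step_times], float(step_times.mean())


def rms_features(trace: AccelerationTrace, segment: WalkSegment) -> tuple[float, float, float]:
    """Per-axis RMS of mean-removed walking acceleration: (AP, V, ML), in g.

    The mean is removed per axis over the walking segment only, so the
    constant gravity component on the vertical axis does not enter the RMS.
    """
    sel = (trace.time >= segment.start_time) & (trace.time <= segment.stop_time)
    if not sel.any():
        raise InvalidParameterError("walking segment contains no samples")
    seg = trace.acc[sel]
    centered = seg - seg.mean(axis=0)
    rms = np.sqrt((centered**2).mean(axis=0))
    return float(rms[0]), float(rms[2]), float(rms[1])  # (AP, V, ML)


def extract_gait_features(
    raw: AccelerationTrace,
    distance: float = 5.0,
    cutoff: float = 6.0,
    order: int = 4,
    window: float = 0.5,
    multiplier: float = 3.0,
    standstill_duration: float = 3.0,
) -> tuple[GaitFeatures, WalkSegment]:
    """Full chain: filter -> calibrate -> detect -> speed, steps, RMS."""
    filtered = lowpass_filter(raw, cutoff=cutoff, order=order)
    calib = calibrate_standstill(
        filtered, window=window, standstill_duration=standstill_duration, multiplier=multiplier
    )
    segment = detect_walk_bounds(filtered, calib, window=window, distance=distance)
    velocity = gait_speed(segment)
    step_times, mean_step = detect_steps(filtered, segment)
    rms_ap, rms_v, rms_ml = rms_features(filtered, segment)
    features = GaitFeatures(
        velocity=velocity,
        step_times=step_times,
        mean_step_time=mean_step,
        rms_ap=rms_ap,
        rms_v=rms_v,
        rms_ml=rms_ml,
    )
    return features, segment
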