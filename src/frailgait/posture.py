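"""Postural complexity and sway dispersion from quiet-stance recordings.

Approximate entropy (ApEn) quantifies the regularity of a time series: the
likelihood that runs of ``m`` consecutive samples that match within a
tolerance ``d`` still match when extended to ``m + 1`` samples. Low values
mean regular, predictable signals (a noiseless sine approaches 0); irregular
signals score high. The tolerance is expressed as a fraction of the series
standard deviation so that ApEn is invariant under affine rescaling.

Center-of-pressure-like sway series are approximated from the mean-removed
planar (AP, ML) accelerations of a pelvis-worn phone, scaled to millimetres;
this *acceleration proxy* is tagged as such in outputs because no direct
force-plate measurement is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import chi2

from .errors import InvalidParameterError
from .trace import AccelerationTrace


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters.

    Attributes
    ----------
    m : int
        Pattern (embedding) length; default 2.
    tolerance_fraction : float
        Similarity tolerance as a fraction of the series SD; default 0.2.
    """

    m: int = 2
    tolerance_fraction: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise InvalidParameterError("pattern length m must be >= 1")
        if not (0 < self.tolerance_fraction < 1):
            raise InvalidParameterError("tolerance_fraction must lie in (0, 1)")


@dataclass
class SwayTrace:
    """Planar sway series (AP, ML) in millimetres plus the resultant radius."""

    ap: np.ndarray
    ml: np.ndarray
    sampling_rate: float
    derivation: str = "acceleration-proxy"
    resultant: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ap = np.asarray(self.ap, float)
        self.ml = np.asarray(self.ml, float)
        if self.ap.shape != self.ml.shape:
            raise InvalidParameterError("AP and ML series must have equal length")
        if not (np.isfinite(self.ap).all() and np.isfinite(self.ml).all()):
            raise InvalidParameterError("sway series must be finite")
        self.resultant = np.hypot(self.ap, self.ml)

    @property
    def n_samples(self) -> int:
        return self.ap.size


@dataclass
class PostureFeatures:
    apen_ml: float
    apen_ap: float
    apen_v: float
    apen_r: float
    sway_path_length: float  # mm
    sway_area: float  # mm^2
    mean_sway_radius: float  # mm
    mean_sway_velocity: float  # mm/s
    sway_sd: float  # mm


def _phi(x: np.ndarray, k: int, d: float) -> float:
    """Mean log fraction of length-k patterns within Chebyshev distance d."""
    n_vec = x.size - k + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, k)
    dist = cdist(emb, emb, metric="chebyshev")
    counts = (dist <= d).sum(axis=1)  # self-match always included
    return float(np.log(counts / n_vec).mean())


def approximate_entropy(series: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """Approximate entropy ApEn(N, m, d) of a scalar series.

    ApEn = Phi^m(d) - Phi^(m+1)(d), where Phi^k(d) is the average natural log
    of the fraction of length-k embedded vectors lying within Chebyshev
    distance ``d = tolerance_fraction * SD(series)`` of each template vector,
    self-matches included (the original Pincus convention, which keeps every
    count positive).

    A constant series (zero SD) returns 0 with a warning: every pattern is
    identical at both lengths, so the series is perfectly regular. The value
    is non-negative for ordinary series, but because Phi^m and Phi^(m+1)
    average over different numbers of templates, marginally negative values
    can occur for very short, highly structured series; they are returned
    as-is rather than clamped.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("series must be one-dimensional")
    m = params.m
    if x.size <= m + 1:
        raise InvalidParameterError(f"series length {x.size} must exceed m + 1 = {m + 1}")
    sd = float(x.std(ddof=0))
    if sd == 0:
        warnings.warn(
            "constant series: ApEn defined as 0 (perfectly regular)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    d = params.tolerance_fraction * sd
    return _phi(x, m, d) - _phi(x, m + 1, d)


def sway_from_acceleration(stance: AccelerationTrace, scale: float = 1000.0) -> SwayTrace:
    """Planar sway proxy from a (filtered) quiet-stance acceleration trace.

    Mean-removed AP and ML accelerations are scaled by ``scale`` (mm per g)
    to a displacement-like series. This stands in for a force-plate
    center-of-pressure trajectory and is tagged ``acceleration-proxy``.
    """
    ap = (stance.ap - stance.ap.mean()) * scale
    ml = (stance.ml - stance.ml.mean()) * scale
    return SwayTrace(ap=ap, ml=ml, sampling_rate=stance.sampling_rate)


def sway_metrics(sway: SwayTrace) -> dict[str, float]:
    """Standard posturographic dispersion metrics of a planar sway series.

    Returns ``sway_path_length`` (sum of successive planar displacements, mm),
    ``mean_sway_velocity`` (path length / recording duration, mm/s),
    ``mean_sway_radius`` (mean planar distance from the scatter centroid, mm),
    ``sway_area`` (area of the 95% confidence ellipse of the planar scatter,
    chi-square with 2 df, mm^2) and ``sway_sd`` (SD of the resultant distance
    from the centroid, mm).
    """
    n = sway.n_samples
    if n < 2:
        raise InvalidParameterError("sway metrics need at least 2 samples")
    dx = np.diff(sway.ap)
    dy = np.diff(sway.ml)
    path_length = float(np.hypot(dx, dy).sum())
    duration = (n - 1) / sway.sampling_rate
    velocity = path_length / duration
    cx, cy = sway.ap.mean(), sway.ml.mean()
    radii = np.hypot(sway.ap - cx, sway.ml - cy)
    mean_radius = float(radii.mean())
    sway_sd = float(radii.std(ddof=0))
    cov = np.cov(np.vstack([sway.ap, sway.ml]), ddof=1)
    eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    area = float(np.pi * chi2.ppf(0.95, df=2) * np.sqrt(eigvals[0] * eigvals[1]))
    return {
        "sway_path_length": path_length,
        "mean_sway_velocity": velocity,
        "mean_sway_radius": mean_radius,
        "sway_area": area,
        "sway_sd": sway_sd,
    }


def posture_features(
    stance_filtered: AccelerationTrace,
    params: ApEnParams = ApEnParams(),
    scale: float = 1000.0,
) -> PostureFeatures:
    """All posture features from a filtered quiet-stance trace.

    ApEn is computed on the sway-proxy AP and ML series, on the mean-removed
    vertical acceleration, and on the planar resultant sway series; the
    dispersion metrics come from the planar proxy.
    """
    sway = sway_from_acceleration(stance_filtered, scale=scale)
    v = stance_filtered.v - stance_filtered.v.mean()
    metrics = sway_metrics(sway)
    return PostureFeatures(
        apen_ml=approximate_entropy(sway.ml, params),
        apen_ap=approximate_entropy(sway.ap, params),
        apen_v=approximate_entropy(v, params),
        apen_r=approximate_entropy(sway.resultant, params),
        **metrics,
    )
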