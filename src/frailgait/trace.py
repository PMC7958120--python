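"""Tri-axial acceleration traces and their on-disk delimited format.

The shared file format is plain delimited text with a mandatory header row
``time_s,acc_ap_g,acc_ml_g,acc_v_g``: time in seconds and acceleration in
units of g along the anatomical anterior-posterior (AP), medial-lateral (ML)
and vertical (V) axes of a pelvis-worn phone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, TraceParseError

TRACE_COLUMNS = ("time_s", "acc_ap_g", "acc_ml_g", "acc_v_g")

#: maximum tolerated deviation from uniform sampling, in seconds
_JITTER_TOL = 1e-6


@dataclass
class AccelerationTrace:
    """Uniformly sampled tri-axial acceleration.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing and uniform.
    acc : ndarray, shape (n, 3)
        Acceleration in g; columns are (AP, ML, V).
    sampling_rate : float
        Sampling frequency in Hz.
    """

    time: np.ndarray
    acc: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise InvalidParameterError("acc must have shape (n, 3) with columns (AP, ML, V)")
        if self.time.shape[0] != self.acc.shape[0]:
            raise InvalidParameterError("time and acc lengths differ")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise InvalidParameterError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > _JITTER_TOL:
                raise InvalidParameterError(
                    "non-uniform sampling: jitter exceeds 1e-6 s relative to sampling_rate"
                )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    @property
    def ap(self) -> np.ndarray:
        return self.acc[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.acc[:, 1]

    @property
    def v(self) -> np.ndarray:
        return self.acc[:, 2]

    def replace_acc(self, acc: np.ndarray) -> "AccelerationTrace":
        """Return a new trace with the same time base and new acceleration."""
        return AccelerationTrace(self.time.copy(), np.asarray(acc, float), self.sampling_rate)

    # -- delimited-text round trip ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "acc_ap_g": self.acc[:, 0],
                "acc_ml_g": self.acc[:, 1],
                "acc_v_g": self.acc[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sampling_rate: float | None = None) -> "AccelerationTrace":
        for col in TRACE_COLUMNS:
            if col not in frame.columns:
                raise TraceParseError(f"trace is missing required column {col!r}")
        time = frame["time_s"].to_numpy(dtype=float)
        if sampling_rate is None:
            if time.size < 2:
                raise TraceParseError("cannot infer sampling rate from fewer than 2 samples")
            sampling_rate = 1.0 / float(np.median(np.diff(time)))
        acc = frame[["acc_ap_g", "acc_ml_g", "acc_v_g"]].to_numpy(dtype=float)
        return cls(time, acc, sampling_rate)

    @classmethod
    def from_csv(cls, path: str | Path, sampling_rate: float | None = None) -> "AccelerationTrace":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - delegated to pandas
            raise TraceParseError(f"cannot parse trace file {path}: {exc}") from exc
        return cls.from_frame(frame, sampling_rate)


def make_time(n_samples: int, sampling_rate: float) -> np.ndarray:
    """Uniform time vector of ``n_samples`` at ``sampling_rate`` Hz, from 0."""
    return np.arange(n_samples, dtype=float) / float(sampling_rate)
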