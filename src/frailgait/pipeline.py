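"""End-to-end orchestration of one preoperative assessment.

A single :class:`PipelineConfig` carries every stage parameter (defaults are
the protocol constants: 50 Hz sampling, 6 Hz 4th-order zero-phase low-pass,
0.5 s detection window, ApEn m = 2 with tolerance 0.2 x SD, 0.833 m/s
frailty threshold, 5 m walkway, 30 s stance) and :func:`run_assessment`
executes filter -> calibrate -> detect -> gait features -> ApEn / sway ->
frailty label -> adverse score, producing a report that is reproducible
bit-identically from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import InvalidParameterError, StageError
from .gait import GaitFeatures, WalkSegment, extract_gait_features, lowpass_filter
from .outcomes import (
    PUBLISHED_CUTOFFS,
    AdverseScoreModel,
    classify_frailty,
)
from .posture import ApEnParams, PostureFeatures, posture_features
from .trace import AccelerationTrace

logger = logging.getLogger("frailgait")


@dataclass
class PipelineConfig:
    sampling_rate: float = 50.0
    filter_cutoff: float = 6.0
    filter_order: int = 4
    detection_window: float = 0.5
    detection_multiplier: float = 3.0
    standstill_duration: float = 3.0
    apen_m: int = 2
    apen_tolerance_fraction: float = 0.2
    frailty_threshold: float = 0.833
    walk_distance: float = 5.0
    stance_duration: float = 30.0
    sway_scale: float = 1000.0  # mm per g
    outcome_aggregation: str = "sum"
    seed: int = 0

    def validate(self) -> None:
        if self.filter_cutoff >= self.sampling_rate / 2:
            raise InvalidParameterError("filter_cutoff must be below Nyquist")
        if self.filter_cutoff <= 0 or self.filter_order < 1:
            raise InvalidParameterError("invalid filter parameters")
        if self.detection_window <= 0 or self.detection_multiplier < 1:
            raise InvalidParameterError("invalid detection parameters")
        if self.apen_m < 1 or not (0 < self.apen_tolerance_fraction < 1):
            raise InvalidParameterError("invalid ApEn parameters")
        if self.frailty_threshold <= 0 or self.walk_distance <= 0:
            raise InvalidParameterError("invalid clinical parameters")
        if self.outcome_aggregation not in ("sum", "max"):
            raise InvalidParameterError("outcome_aggregation must be 'sum' or 'max'")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class AssessmentReport:
    """One subject's full preoperative assessment."""

    subject_id: str
    gait: GaitFeatures
    posture: PostureFeatures
    walk_segment: WalkSegment
    frailty: str
    adverse_score: float
    cutoff_flags: dict[str, bool]
    config_hash: str
    seed: int
    software_version: str = field(default=__version__)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "frailty": self.frailty,
            "adverse_score": self.adverse_score,
            "gait": dataclasses.asdict(self.gait),
            "posture": dataclasses.asdict(self.posture),
            "walk_segment": dataclasses.asdict(self.walk_segment),
            "cutoff_flags": self.cutoff_flags,
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "software_version": self.software_version,
                "sway_derivation": "acceleration-proxy",
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(name: str, subject_id: str, fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, subject_id, exc) from exc
    logger.debug("stage %s ok for subject %s", name, subject_id)
    return result


def run_assessment(
    stance_path: str | Path,
    walk_path: str | Path,
    config: PipelineConfig,
    subject_id: str = "subject",
    model: AdverseScoreModel | None = None,
) -> AssessmentReport:
    """Run the full assessment on one subject's stance + walk recordings."""
    config.validate()
    logger.debug(
        "run_assessment subject=%s config_hash=%s seed=%d",
        subject_id, config.config_hash, config.seed,
    )
    model = model or AdverseScoreModel.published()

    walk_raw = _stage("parse-walk", subject_id, AccelerationTrace.from_csv, walk_path)
    stance_raw = _stage("parse-stance", subject_id, AccelerationTrace.from_csv, stance_path)

    gait, segment = _stage(
        "gait-features",
        subject_id,
        extract_gait_features,
        walk_raw,
        distance=config.walk_distance,
        cutoff=config.filter_cutoff,
        order=config.filter_order,
        window=config.detection_window,
        multiplier=config.detection_multiplier,
        standstill_duration=config.standstill_duration,
    )
    stance_filtered = _stage(
        "filter-stance", subject_id, lowpass_filter, stance_raw,
        cutoff=config.filter_cutoff, order=config.filter_order,
    )
    posture = _stage(
        "posture-features",
        subject_id,
        posture_features,
        stance_filtered,
        ApEnParams(m=config.apen_m, tolerance_fraction=config.apen_tolerance_fraction),
        scale=config.sway_scale,
    )
    frailty = _stage(
        "classify", subject_id, classify_frailty, gait.velocity, config.frailty_threshold
    )
    feature_row = {
        "smartphone_velocity": gait.velocity,
        "rms_ap": gait.rms_ap,
        "rms_v": gait.rms_v,
        "apen_ml_cop": posture.apen_ml,
        "apen_r_cop": posture.apen_r,
        "step_time": gait.mean_step_time,
    }
    score = _stage("score", subject_id, model.predict, feature_row)
    flags = {
        f"{var}{direction}{threshold}": bool(
            feature_row[var] <= threshold if direction == "<=" else feature_row[var] > threshold
        )
        for var, direction, threshold in PUBLISHED_CUTOFFS
    }
    return AssessmentReport(
        subject_id=subject_id,
        gait=gait,
        posture=posture,
        walk_segment=segment,
        frailty=frailty,
        adverse_score=score,
        cutoff_flags=flags,
        config_hash=config.config_hash,
        seed=config.seed,
    )
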