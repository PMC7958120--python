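"""Frailty classification, outcome scoring, and the adverse-outcome model.

The clinical pieces: gait-speed frailty classification (frail below
0.833 m/s, with a severe 0.65 m/s threshold also defined in the literature),
a severity-weighted postoperative outcome score, the published five-predictor
linear adverse-outcome score, OLS refitting with R^2 / Mallows' Cp / VIF
diagnostics, group comparisons, and exhaustive cut-point analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import InvalidParameterError, MissingFeatureError, SingularDesignError

#: gait-speed threshold (m/s) separating frail from non-frail
FRAILTY_THRESHOLD = 0.833
#: stricter literature threshold (m/s) flagging severe frailty
SEVERE_FRAILTY_THRESHOLD = 0.65

#: the five predictors of the adverse-outcome score, in canonical order
PREDICTORS = ("rms_ap", "rms_v", "apen_ml_cop", "apen_r_cop", "step_time")

#: postoperative event severity weights, highest = worst
SEVERITY_WEIGHTS: dict[str, int] = {
    "death": 7,
    "prolonged_ventilation": 6,  # ventilation > 24 h
    "prolonged_stay": 5,  # hospital stay > 14 days
    "snf_discharge": 4,  # discharge to a skilled nursing facility
    "stroke": 3,  # neurological deficit > 72 h
    "renal_failure": 3,  # creatinine > 2 mg/dL
    "reoperation": 2,  # surgical reintervention > 24 h post-op
    "dswi": 1,  # deep sternal wound infection
}

EVENT_NAMES = tuple(SEVERITY_WEIGHTS)


def classify_frailty(speed: float, threshold: float = FRAILTY_THRESHOLD) -> str:
    """Label a subject frail/non-frail from 5-m gait speed.

    Frail iff ``speed < threshold`` (strictly); a subject walking at exactly
    the threshold is non-frail.
    """
    if speed <= 0:
        raise InvalidParameterError("gait speed must be positive")
    return "frail" if speed < threshold else "non-frail"


@dataclass(frozen=True)
class OutcomeRecord:
    """Boolean postoperative event flags for one patient."""

    death: bool = False
    prolonged_ventilation: bool = False
    prolonged_stay: bool = False
    snf_discharge: bool = False
    stroke: bool = False
    renal_failure: bool = False
    reoperation: bool = False
    dswi: bool = False

    def events(self) -> list[str]:
        return [name for name in EVENT_NAMES if getattr(self, name)]


def outcome_score(record: OutcomeRecord, aggregation: Literal["sum", "max"] = "sum") -> int:
    """Severity-weighted outcome score from the event flags.

    ``sum`` adds the weights of all flagged events (a composite burden);
    ``max`` takes the single worst event. A record with no events scores 0.
    """
    weights = [SEVERITY_WEIGHTS[name] for name in record.events()]
    if not weights:
        return 0
    if aggregation == "sum":
        return int(sum(weights))
    if aggregation == "max":
        return int(max(weights))
    raise InvalidParameterError(f"unknown aggregation {aggregation!r}")


@dataclass
class AdverseScoreModel:
    """Linear adverse-outcome score: intercept + 5 gait/posture predictors.

    The published instance is
    ``score = 44.13 - 26.96*RMS_AP - 28.29*RMS_V + 13.33*ApEn_ML_COP
    - 46.85*ApEn_R_COP + 5.35*StepTime``.
    """

    intercept: float
    coefficients: dict[str, float]
    r_squared: float | None = None
    mallows_cp: float | None = None
    vif: dict[str, float] = field(default_factory=dict)
    provenance: str = "refitted"

    def __post_init__(self):
        missing = [p for p in PREDICTORS if p not in self.coefficients]
        if missing:
            raise InvalidParameterError(f"model lacks coefficients for {missing}")

    @classmethod
    def published(cls) -> "AdverseScoreModel":
        return cls(
            intercept=44.13,
            coefficients={
                "rms_ap": -26.96,
                "rms_v": -28.29,
                "apen_ml_cop": 13.33,
                "apen_r_cop": -46.85,
                "step_time": 5.35,
            },
            provenance="published",
        )

    @property
    def vif_flag(self) -> bool:
        return any(v >= 5 for v in self.vif.values())

    def predict(self, row: Mapping[str, float]) -> float:
        """Evaluate the score at one feature row; see :func:`predict_adverse_score`."""
        return predict_adverse_score(row, self)

    # -- plain-text key-value serialization ---------------------------------

    def to_text(self) -> str:
        lines = [f"provenance: {self.provenance}", f"intercept: {self.intercept!r}"]
        lines += [f"{name}: {self.coefficients[name]!r}" for name in PREDICTORS]
        if self.r_squared is not None:
            lines.append(f"r_squared: {self.r_squared!r}")
        if self.mallows_cp is not None:
            lines.append(f"mallows_cp: {self.mallows_cp!r}")
        for name, v in self.vif.items():
            lines.append(f"vif_{name}: {v!r}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "AdverseScoreModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
        vif = {
            k[len("vif_"):]: float(v) for k, v in kv.items() if k.startswith("vif_")
        }
        return cls(
            intercept=float(kv["intercept"]),
            coefficients={name: float(kv[name]) for name in PREDICTORS},
            r_squared=float(kv["r_squared"]) if "r_squared" in kv else None,
            mallows_cp=float(kv["mallows_cp"]) if "mallows_cp" in kv else None,
            vif=vif,
            provenance=kv.get("provenance", "refitted"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AdverseScoreModel":
        return cls.from_text(Path(path).read_text())


def predict_adverse_score(row: Mapping[str, float], model: AdverseScoreModel) -> float:
    """Linear evaluation of the adverse-outcome score at one feature row."""
    score = model.intercept
    for name in PREDICTORS:
        if name not in row or row[name] is None:
            raise MissingFeatureError(name)
        value = float(row[name])
        if not np.isfinite(value):
            raise MissingFeatureError(name)
        score += model.coefficients[name] * value
    return float(score)


def _vif_table(X: np.ndarray) -> dict[str, float]:
    """VIF per predictor from a design matrix with leading constant column."""
    out = {}
    for j, name in enumerate(PREDICTORS, start=1):
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = float(variance_inflation_factor(X, j))
        except Exception:
            v = float("inf")
        out[name] = float("inf") if not np.isfinite(v) else v
    return out


def fit_adverse_model(
    features: pd.DataFrame, scores: Sequence[float]
) -> AdverseScoreModel:
    """Refit the adverse-outcome score by OLS, with fit diagnostics.

    ``features`` must contain the five predictor columns; ``scores`` is the
    severity-weighted outcome per row. Reports R^2, Mallows' Cp relative to
    the full five-predictor model (equal to the parameter count, 6, by
    construction for the full fit itself), and per-predictor VIF with a flag
    raised when any VIF >= 5.
    """
    missing = [p for p in PREDICTORS if p not in features.columns]
    if missing:
        raise MissingFeatureError(missing[0])
    y = np.asarray(scores, dtype=float)
    n = len(features)
    if n != y.size:
        raise InvalidParameterError("features and scores lengths differ")
    if n <= len(PREDICTORS) + 1:
        raise InvalidParameterError(
            f"need more than {len(PREDICTORS) + 1} rows to fit, got {n}"
        )
    X = sm.add_constant(features[list(PREDICTORS)].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "singular design: predictor columns are linearly dependent", vif=_vif_table(X)
        )
    fit = sm.OLS(y, X).fit()
    p = X.shape[1]
    sse = float(fit.ssr)
    # Cp against the full 5-predictor model as reference: sigma^2 from this
    # same full fit, so Cp = SSE/sigma^2 - n + 2p = p exactly for the full fit.
    sigma2 = sse / (n - p)
    cp = sse / sigma2 - n + 2 * p if sigma2 > 0 else float(p)
    return AdverseScoreModel(
        intercept=float(fit.params[0]),
        coefficients={name: float(fit.params[j]) for j, name in enumerate(PREDICTORS, 1)},
        r_squared=float(fit.rsquared),
        mallows_cp=float(cp),
        vif=_vif_table(X),
        provenance="refitted",
    )


def compare_groups(
    features: pd.DataFrame,
    labels: Sequence,
    variables: Sequence[str] | None = None,
    test: Literal["welch", "mannwhitney"] = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison: means, SDs, CVs, and a p-value.

    ``labels`` is a binary grouping (e.g. morbid / non-morbid). The default
    test is Welch's unequal-variance t-test; ``mannwhitney`` switches to the
    rank-based Mann-Whitney U. A ``significant`` column marks p < ``alpha``.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise InvalidParameterError(f"need exactly 2 groups, got {len(groups)}")
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InvalidParameterError("each group needs at least 2 subjects")
    if variables is None:
        variables = [c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for var in variables:
        a = features.loc[mask_a, var].to_numpy(dtype=float)
        b = features.loc[mask_b, var].to_numpy(dtype=float)
        if test == "welch":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        elif test == "mannwhitney":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            raise InvalidParameterError(f"unknown test {test!r}")
        if np.isnan(p):  # identical constant groups
            p = 1.0
        rows.append(
            {
                "variable": var,
                f"mean_{groups[0]}": a.mean(),
                f"sd_{groups[0]}": a.std(ddof=1),
                f"cv_{groups[0]}": 100 * a.std(ddof=1) / abs(a.mean()) if a.mean() != 0 else np.nan,
                f"mean_{groups[1]}": b.mean(),
                f"sd_{groups[1]}": b.std(ddof=1),
                f"cv_{groups[1]}": 100 * b.std(ddof=1) / abs(b.mean()) if b.mean() != 0 else np.nan,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass(frozen=True)
class CutoffRule:
    """A single-variable classification rule: positive iff value <=/> threshold."""

    variable: str
    direction: Literal["<=", ">"]
    threshold: float
    sensitivity: float
    specificity: float

    def __post_init__(self):
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise InvalidParameterError("sensitivity/specificity must be in [0, 1]")

    def apply(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values <= self.threshold if self.direction == "<=" else values > self.threshold


def sens_spec_at(values, labels, threshold: float, direction: str) -> tuple[float, float]:
    """Sensitivity and specificity of the rule at one candidate threshold."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = values <= threshold if direction == "<=" else values > threshold
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec


def cutpoint_analysis(
    values: Sequence[float],
    labels: Sequence,
    direction: Literal["<=", ">"] = "<=",
    variable: str = "",
) -> CutoffRule:
    """Optimal single-variable cut-point by exhaustive midpoint scan.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values. The winner maximizes sensitivity + specificity (Youden's J); ties
    are broken toward the rule with the higher sensitivity, then toward the
    first candidate in ascending threshold order.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.size != labels.size:
        raise InvalidParameterError("values and labels lengths differ")
    if labels.all() or not labels.any():
        raise InvalidParameterError("both classes must be present")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise InvalidParameterError("need at least 2 distinct values")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for thr in candidates:
        sens, spec = sens_spec_at(values, labels, thr, direction)
        key = (sens + spec, sens)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    return CutoffRule(
        variable=variable, direction=direction, threshold=float(thr),
        sensitivity=sens, specificity=spec,
    )


#: published single-variable morbidity cut-offs (variable, direction, threshold)
PUBLISHED_CUTOFFS = (
    ("smartphone_velocity", "<=", 0.716),  # m/s
    ("rms_v", "<=", 0.137),  # g
    ("step_time", ">", 0.533),  # s
    ("apen_r_cop", "<=", 1.139),  # unitless
)
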