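"""Exception hierarchy shared across the pipeline stages."""


class FrailGaitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FrailGaitError, ValueError):
    """A parameter violates a stage precondition (e.g. cutoff >= Nyquist)."""


class TraceParseError(FrailGaitError, ValueError):
    """A trace file is malformed; the message names the offending column."""


class CalibrationError(FrailGaitError, ValueError):
    """Stand-still calibration cannot be derived from the recording prefix."""


class NoWalkDetectedError(FrailGaitError, RuntimeError):
    """No window of the recording exceeds the stand-still threshold."""


class TooFewStepsError(FrailGaitError, RuntimeError):
    """Fewer than three step events were found in the walking segment."""


class UnusableTrialError(FrailGaitError, ValueError):
    """A requested trial configuration cannot yield an analyzable recording."""


class MissingFeatureError(FrailGaitError, KeyError):
    """A required model predictor is absent from a feature row."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"missing required predictor column: {column!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"missing required predictor column: {self.column!r}"


class SingularDesignError(FrailGaitError, ValueError):
    """The regression design matrix is rank deficient.

    Carries per-predictor variance inflation factors (``inf`` for perfectly
    collinear columns) so callers can report which predictors collide.
    """

    def __init__(self, message: str, vif: dict | None = None):
        super().__init__(message)
        self.vif = vif or {}
        self.vif_flag = any(v >= 5 for v in self.vif.values()) if self.vif else True


class StageError(FrailGaitError, RuntimeError):
    """Wraps an error raised inside a pipeline stage with context attached."""

    def __init__(self, stage: str, subject_id: str, cause: BaseException):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"[stage={stage}, subject={subject_id}] {cause}")
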