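"""Exception hierarchy for the grading pipeline.

Each exception carries a short machine-readable ``code`` (stable across
releases, usable for dispatch) alongside the human-readable message.
"""


class FlGradeError(Exception):
    """Base class for all pipeline errors."""

    code = "error"

    def __init__(self, message: str | None = None, *, code: str | None = None):
        if code is not None:
            self.code = code
        super().__init__(message or self.code)


class RegistrationError(FlGradeError):
    """Raised when rigid registration cannot produce a usable transform."""


class DetectionError(FlGradeError):
    """Raised on degenerate inputs to the high-power-field detector."""


class ClassificationError(FlGradeError):
    """Raised on invalid inputs to the sub-block / HPF / tissue classifier."""


class StatsError(FlGradeError):
    """Raised on degenerate inputs to the reader-study statistics."""


class SimulationError(FlGradeError):
    """Raised when the synthetic-data generator cannot satisfy its config."""
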