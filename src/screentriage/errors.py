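"""Exception hierarchy.

Validation/configuration problems (bad inputs, bad cut points) are kept
distinct from degenerate-data and undefined-metric conditions so callers —
and the CLI exit codes — can tell user error from data pathology.
"""


class ScreenTriageError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ScreenTriageError):
    """A required column is missing from a visit table."""


class ValidationError(ScreenTriageError):
    """A value violates a domain invariant (score range, BI-RADS code, ...)."""


class ConfigurationError(ScreenTriageError):
    """Inconsistent configuration (cut-point order, rates, scenario names)."""


class DegenerateInputError(ScreenTriageError):
    """Input lacks the structure an operation needs (e.g. a single class)."""


class UndefinedMetricError(ScreenTriageError):
    """A requested metric has a zero denominator."""


class PipelineStageError(ScreenTriageError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
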