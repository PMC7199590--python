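"""Structured exceptions shared across the package.

Every rejected input raises an exception that names what was wrong and,
where applicable, which row/field/column triggered it — no silent coercion.
"""

from __future__ import annotations


class RdwprogError(Exception):
    """Base class for all package errors."""


class SchemaError(RdwprogError):
    """A required column is missing or an input table has the wrong layout."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class ValidationError(RdwprogError):
    """A value violates a domain invariant; identifies row and field."""

    def __init__(self, message: str, row: object = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class ConfigError(RdwprogError):
    """Invalid generator or pipeline configuration."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class CalibrationError(RdwprogError):
    """Intercept calibration could not reach the target rate."""


class DegenerateOutcomeError(RdwprogError):
    """The outcome is constant; a logistic model cannot be fitted."""


class CollinearityError(RdwprogError):
    """The design matrix is rank deficient; names the offending columns."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class NotConvergedError(RdwprogError):
    """Results were requested from a model whose fit did not converge."""


class DegenerateLabelsError(RdwprogError):
    """Discrimination metrics need at least one event and one non-event."""


class PairingError(RdwprogError):
    """Paired model comparisons need risk vectors over the same patients."""


class DegenerateMarginError(RdwprogError):
    """A contingency table has an all-zero row or column margin."""


class EnumerationBoundError(RdwprogError):
    """Exact enumeration would exceed the configured table bound."""


class UnidentifiableError(RdwprogError):
    """A model's variance components cannot be identified from the data."""


class PipelineError(RdwprogError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
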