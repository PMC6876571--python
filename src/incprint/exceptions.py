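"""Exception hierarchy for the incprint package.

All errors raised by the package derive from :class:`IncPrintError`, so
callers can catch one base class at pipeline boundaries.
"""


class IncPrintError(Exception):
    """Base class for all incprint errors."""


class FormatError(IncPrintError):
    """A file does not conform to the expected tabular format."""


class ValidationError(IncPrintError):
    """A row-level value is invalid (non-numeric, negative, out of range)."""


class IntegrityError(IncPrintError):
    """Cross-record consistency violated (duplicate keys, unknown proteins)."""


class LayoutError(IncPrintError):
    """Plate-map layout is inconsistent (wrong plate count or shape)."""


class ContractError(IncPrintError):
    """An operation was called on a record that violates its precondition."""


class DegenerateDistributionError(IncPrintError):
    """A threshold cannot be derived from a degenerate distribution."""


class UndefinedCorrelationError(IncPrintError):
    """Correlation undefined because one replicate vector has zero variance."""


class InsufficientDataError(IncPrintError):
    """Fewer analyzed records than an operation requires."""


class InsufficientOverlapError(IncPrintError):
    """Too few common binders found in a target dataset to normalize it."""


class DegenerateControlError(IncPrintError):
    """The common-binder median is zero; normalization is undefined."""


class DegenerateBackgroundError(IncPrintError):
    """The score MAD is zero; the robust background cutoff is undefined."""


class PipelineError(IncPrintError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
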