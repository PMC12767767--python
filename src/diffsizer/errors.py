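"""Exception hierarchy.

Every failure the analysis can report is a subclass of :class:`DiffsizerError`,
so callers (and the CLI) can distinguish analysis failures from programming
errors with a single ``except``.
"""


class DiffsizerError(Exception):
    """Base class for all analysis errors."""


class DomainError(DiffsizerError, ValueError):
    """A physical quantity is outside its admissible domain."""


class SchemaError(DiffsizerError):
    """The workbook is missing a required metadata key or sheet."""


class FormatError(DiffsizerError):
    """A profile sheet violates the workbook dialect (e.g. non-uniform x)."""


class InsufficientDataError(DiffsizerError):
    """Fewer usable measurement points than the analysis requires."""


class DegenerateProfileError(DiffsizerError):
    """A profile carries no usable structure (e.g. everything below the crop band)."""


class WallNotFoundError(DiffsizerError):
    """A channel sidewall could not be localized inside the trace."""


class BaselineError(DiffsizerError):
    """No outside section is available to estimate the fluorescence baseline."""


class NoSignalError(DiffsizerError):
    """Fluorescent trace is flat: no peak above baseline + 3 sigma."""


class FitFailedError(DiffsizerError):
    """Every multi-start attempt of a mixture fit failed."""


class InfeasibleBoundsError(DiffsizerError):
    """Sequential sigma bounds collapsed against the global cap."""


class NonPhysicalSlopeError(DiffsizerError):
    """The variance-time line has a non-positive slope; no radius is emitted."""


class NoResultError(DiffsizerError):
    """No component track produced a usable sizing result."""


class UsageError(DiffsizerError):
    """Caller error: unknown format, bad configuration value, ..."""


class StageError(DiffsizerError):
    """Wraps a stage failure with the stage name and measurement-point label."""

    def __init__(self, stage: str, label: str | None, cause: Exception):
        self.stage = stage
        self.label = label
        self.cause = cause
        where = f"{stage}" + (f" at point {label}" if label else "")
        super().__init__(f"{where}: {cause}")
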