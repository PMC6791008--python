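"""Exception hierarchy shared across the pipeline."""


class ThymospecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThymospecError):
    """Invalid configuration (bad group name, bad correlation matrix, ...)."""


class ValidationError(ThymospecError):
    """Input data violates a documented contract (schema, vocabulary)."""


class PlateFormatError(ThymospecError):
    """A qPCR plate is missing required wells, targets, or columns."""


class PlateContaminationError(ThymospecError):
    """A no-template control amplified below the contamination Cq cutoff."""


class InsufficientStandardsError(ThymospecError):
    """Fewer than three distinct standard dilution points for a target."""


class AssayFailureError(ThymospecError):
    """Standard-curve fit produced a physically impossible result (slope >= 0)."""


class InsufficientReplicatesError(ThymospecError):
    """A replicate group has fewer than two usable wells."""


class UndetectedSubgroupError(ThymospecError):
    """An operation that requires a detected TRBV subgroup got an undetected one."""


class ExtrapolationWarning(UserWarning):
    """Interpolated quantity lies >1 log10 outside the standard range."""
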