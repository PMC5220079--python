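"""Exception hierarchy shared across the package."""


class SpectraQCError(Exception):
    """Base class for all spectraqc errors."""


class DataFormatError(SpectraQCError):
    """A file cell that must be numeric (or blank) is not."""


class GroupingError(SpectraQCError):
    """Row count is not a multiple of the samples-per-scan block size."""


class OrderingError(SpectraQCError):
    """Wavelength header is not strictly increasing."""


class LayoutError(SpectraQCError):
    """Response table lacks the three code columns + >=1 variable layout."""


class LookupError(SpectraQCError):
    """Unknown plot id, sample index, SRI name or variable name."""


class DomainError(SpectraQCError):
    """Predictor values outside a model's domain (e.g. x <= 0 for ln x)."""


class InsufficientDataError(SpectraQCError):
    """Fewer observations than model parameters (DFE <= 0)."""


class RegistrationError(SpectraQCError):
    """Duplicate SRI name in a registry."""


class ExpressionError(SpectraQCError):
    """Malformed SRI expression, or a band used but not declared."""


class ConfigError(SpectraQCError):
    """Invalid simulation or filter configuration."""
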