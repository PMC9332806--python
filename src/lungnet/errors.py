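"""Exception hierarchy.

Every error raised by the package derives from :class:`LungNetError`, so
callers can catch one type at the pipeline boundary. Subclasses are split by
contract: metadata problems on input files, geometric range violations,
configuration mistakes, and statistical insufficiency.
"""


class LungNetError(Exception):
    """Base class for all package errors."""


class InvalidMetadataError(LungNetError):
    """A DICOM attribute is present but unusable (e.g. zero rescale slope)."""


class MissingMetadataError(LungNetError):
    """A required DICOM attribute (pixel data, rescale tags, spacing) is absent."""


class CropOutOfBoundsError(LungNetError):
    """The requested crop window does not fit inside the source slice."""


class DomainError(LungNetError):
    """A numeric argument lies outside its mathematical domain."""


class ConfigurationError(LungNetError):
    """A user-supplied name or parameter does not match the configuration."""


class InsufficientDataError(LungNetError):
    """Too few observations to perform a fit or a two-sample test."""


class UndefinedStatisticError(LungNetError):
    """The requested statistic is undefined for this input (e.g. R^2 with zero
    total variance, or a Welch test where both sample variances vanish)."""


class EncodingError(LungNetError):
    """Values cannot be represented in the requested output encoding."""
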