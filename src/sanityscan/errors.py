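"""Exception hierarchy for the sanity-scan toolkit."""


class SanityScanError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SanityScanError):
    """A file could not be parsed as the expected format."""


class IntegrityError(SanityScanError):
    """Input data is internally inconsistent (e.g. a gapped DICOM series)."""


class ParameterError(SanityScanError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class DegenerateDataError(SanityScanError):
    """Data is degenerate for the requested operation (e.g. zero variance)."""


class AlignmentError(SanityScanError):
    """A mask does not share its volume's grid."""


class EmptyTargetError(SanityScanError):
    """A target-dependent operation received an empty segmentation mask."""


class ConfigurationError(SanityScanError):
    """A required input (mask, matrix cell, ...) is missing for the request."""


class ContractError(SanityScanError):
    """Shapes or dimensions violate an interface contract."""


class StratificationError(SanityScanError):
    """A class is too small to stratify into the requested folds."""


class UndefinedAUCError(SanityScanError):
    """AUC is undefined because only one class is present."""


class GeometryError(SanityScanError):
    """A simulated structure does not fit inside its grid."""


class InsufficientSlicesError(SanityScanError):
    """An operation needs more slices than the volume provides."""
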