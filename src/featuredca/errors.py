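"""Exception hierarchy shared across the package."""


class FeatureDCAError(Exception):
    """Base class for package-specific errors."""


class AlignmentShapeError(FeatureDCAError, ValueError):
    """Rows of an alignment (or paired arrays) have inconsistent shapes."""


class EmptyInputError(FeatureDCAError, ValueError):
    """An input file or collection contained no records."""


class ParameterError(FeatureDCAError, ValueError):
    """A parameter is outside its documented range."""


class ModelFormatError(FeatureDCAError, ValueError):
    """A model archive is missing arrays or carries inconsistent metadata."""


class CoordinateMappingError(FeatureDCAError, ValueError):
    """A mutation position cannot be mapped onto the alignment columns."""


class InsufficientOverlapError(FeatureDCAError, ValueError):
    """Too few rows matched between predicted and experimental tables."""
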