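"""Exception hierarchy shared across the package."""


class LcmapError(Exception):
    """Base class for all lcmap-specific errors."""


class GridMismatchError(LcmapError):
    """Two volumes that must share a voxel grid do not (shape or affine)."""


class DimensionalityError(LcmapError):
    """An image does not have the expected number of dimensions."""


class InsufficientDataError(LcmapError):
    """Not enough observations for the requested fit or test."""


class DegenerateDataError(LcmapError):
    """Input data carry no usable variation (e.g. constant values)."""


class MaskOverlapError(LcmapError):
    """Masks that must be disjoint overlap."""


class ConfigurationError(LcmapError):
    """A pipeline or model configuration is invalid or incomplete."""


class NormalizationError(LcmapError):
    """A normalization denominator (e.g. brainstem volume) is empty/zero."""


class SchemaError(LcmapError):
    """A tabular input is missing required columns or has invalid values."""
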