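"""Exception hierarchy shared across the package."""


class RadsurvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RadsurvError):
    """A file exists but does not hold a readable image or table."""


class AlignmentError(RadsurvError):
    """A mask and a volume do not share the same voxel grid."""


class DomainError(RadsurvError):
    """Input violates a precondition of the operation (empty ROI, bad spacing...)."""


class DegenerateROIError(DomainError):
    """The ROI has too few valid voxels for the requested statistic."""


class SchemaError(RadsurvError):
    """A table is missing required columns or has mismatched lengths."""


class ConfigError(RadsurvError):
    """An invalid configuration value (rates outside [0,1], empty grids...)."""
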