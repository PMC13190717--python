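"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`TremornetError`
so callers can distinguish contract violations from genuine bugs.
"""


class TremornetError(Exception):
    """Base class for all tremornet errors."""


class DimensionalityError(TremornetError):
    """Input volume is not 3-D."""


class UnsupportedOrientationError(TremornetError):
    """Volume header carries rotation/shear; only axis-aligned grids are handled."""


class GridMismatchError(TremornetError):
    """Maps that must share a grid/mask do not."""


class DegenerateNormalizationError(TremornetError):
    """Reference-region mean is zero; intensity normalization undefined."""


class UnsupportedResamplingError(TremornetError):
    """Target voxel size is not an integer multiple of the source size."""


class AsymmetricGridError(TremornetError):
    """Grid cannot be reflected about the midsagittal plane x = 0."""


class PlacementError(TremornetError):
    """Synthetic hub placed outside the grid."""


class ConfigError(TremornetError):
    """Invalid generator or pipeline configuration."""


class DegenerateGeometryError(TremornetError):
    """Duplicate voxel coordinates make inverse-distance weights undefined."""


class ResourceCapError(TremornetError):
    """In-mask voxel count exceeds the dense spatial-weights cap."""


class UndefinedStatisticError(TremornetError):
    """Statistic undefined for the input (e.g. Moran's I of a constant map)."""


class DecompositionError(TremornetError):
    """Eigendecomposition of the spatial weight matrix failed."""


class SupportError(TremornetError):
    """Degenerate or too-small voxel support for a similarity/alignment score."""


class DegenerateDesignError(TremornetError):
    """Constant covariate or rank-deficient regression design."""


class InsufficientDataError(TremornetError):
    """Too few observations for the requested degrees of freedom."""


class StandardizationError(TremornetError):
    """Zero cohort standard deviation; z-scoring undefined."""


class UndefinedImprovementError(TremornetError):
    """Relative improvement undefined (baseline score is zero)."""


class EmptyROIError(TremornetError):
    """VTA-overlap ROI empty at the requested minimum overlap."""


class DegenerateFitError(TremornetError):
    """No condition contrast to fit (e.g. On == Off for every subject)."""
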