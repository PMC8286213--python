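"""Exception hierarchy for the petharm pipeline.

Each stage raises a subclass of :class:`PetharmError` so callers (and the
CLI) can distinguish configuration problems from data-driven failures such
as a low-contrast sphere that cannot be delineated.
"""


class PetharmError(Exception):
    """Base class for all petharm errors."""


class InvalidIsotopeError(PetharmError):
    """Isotope parameters are unphysical (e.g. non-positive half-life)."""


class UndefinedRatioError(PetharmError):
    """Sphere-to-background ratio requested with zero background activity."""


class InvalidParameterError(PetharmError):
    """A numeric parameter is outside its allowed range."""


class GeometryClippedError(PetharmError):
    """The voxel grid does not contain the phantom geometry."""


class SegmentationError(PetharmError):
    """A sphere VOI could not be delineated (contrast too low)."""


class BatteryPlacementError(PetharmError):
    """The background ROI battery cannot be placed without collisions."""


class ProfilesUnavailableError(PetharmError):
    """Sphere footprint too small to draw 1D profiles across it."""


class UndefinedPtvError(PetharmError):
    """Peak-to-valley ratio undefined (non-positive valley)."""


class InvalidReferenceError(PetharmError):
    """A ratio denominator (true concentration / contrast) is invalid."""


class InsufficientDataError(PetharmError):
    """Too few regions, voxels or paired observations for a statistic."""


class IncompatibleResultsError(PetharmError):
    """IQ results with mismatched sphere sets cannot be aggregated."""


class IncompleteLimitsError(PetharmError):
    """A limits table does not cover a requested sphere/metric."""


class InvalidSuvError(PetharmError):
    """Non-positive SUV encountered where a log transform is required."""


class FormatError(PetharmError):
    """An image file or series could not be read unambiguously."""
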