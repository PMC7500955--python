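"""Exception hierarchy shared by all centromorph modules."""


class CentromorphError(Exception):
    """Base class for all errors raised by this package."""


class InvalidCalibrationError(CentromorphError):
    """Non-positive gel size, coverslip size, pixel size or z-step."""


class InvalidInputError(CentromorphError):
    """Input value outside the domain of an operation (e.g. negative distance)."""


class GeometryError(CentromorphError):
    """Requested geometry does not fit the field of view, or a reference
    point (center, segment) lies outside the image."""


class PackingError(CentromorphError):
    """Requested focus density too high to place non-overlapping spots."""


class EmptyImageError(CentromorphError):
    """No above-threshold signal in a channel that must contain structure."""


class NoMeasurementError(CentromorphError):
    """Every candidate measurement was rejected by the resolution filter."""


class NoSignalError(CentromorphError):
    """A 1-D profile never exceeds the measurement threshold."""


class AmbiguousAxisError(CentromorphError):
    """The tubulin mask is too round to define a long axis."""


class UnresolvedWallError(CentromorphError):
    """Fewer than two transverse wall peaks in a diameter scan."""


class InsufficientPeaksError(CentromorphError):
    """Too few wall peaks for the requested shape measurement."""


class DegenerateFitError(CentromorphError):
    """Peak set is degenerate (e.g. collinear) so an ellipse fit is ill-posed."""


class RegionError(CentromorphError):
    """Axial regions cannot be defined from the available measurements."""


class NormalizationError(CentromorphError):
    """Control group mean is zero (or control group empty)."""


class UndersampledError(CentromorphError):
    """Sampling step too coarse for the requested periodicity search range."""


class MissingGroupError(CentromorphError):
    """A requested group label has no measurements."""
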