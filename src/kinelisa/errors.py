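"""Exception hierarchy for kinelisa."""


class KinelisaError(Exception):
    """Base class for all kinelisa errors."""


class DomainError(KinelisaError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class UndefinedHueError(DomainError):
    """Hue requested for an achromatic color (a* = b* = 0)."""


class LoadError(KinelisaError):
    """A frame sequence could not be loaded; the message names the offending frame."""


class GeometryError(KinelisaError):
    """A chamber ROI does not fit inside the frame, or ROIs overlap."""


class DegenerateReferenceError(KinelisaError):
    """The reference (initial) value of a ratio series is zero."""


class CorrectionFailureError(KinelisaError):
    """Artifact correction flagged every sample after the first; trace unusable."""


class RangeError(KinelisaError, ValueError):
    """A query time lies outside the span of a trace (extrapolation refused)."""


class FitError(KinelisaError):
    """A calibration fit could not be performed."""


class ConfigError(KinelisaError, ValueError):
    """Invalid synthetic-assay or run configuration."""
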