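"""Exception hierarchy for the pwvloop pipeline.

Every stage raises a distinct subclass so the orchestrator can report the
failing stage together with run/beat provenance.
"""


class PwvloopError(Exception):
    """Base class for all pwvloop errors."""


class ParseError(PwvloopError):
    """Input file could not be read or decoded."""


class CalibrationError(PwvloopError):
    """Required calibration metadata is missing or invalid."""


class ShapeError(PwvloopError):
    """Pixel matrices have inconsistent shapes."""


class GeometryError(PwvloopError):
    """Requested rendering geometry does not fit inside the image."""


class EcgExtractionError(PwvloopError):
    """The ECG strip contains no usable trace."""


class TracingQualityError(PwvloopError):
    """Too many columns could not be traced; threshold likely needs adjusting."""


class InsufficientDataError(PwvloopError):
    """Not enough defined points for spline fitting."""


class AnatomyError(PwvloopError):
    """Anatomically implausible tracing (e.g. crossing walls)."""


class SegmentationError(PwvloopError):
    """Beat segmentation requires at least two R-peaks."""


class OnsetDetectionError(PwvloopError):
    """No systolic upstroke could be located in a beat."""


class InsufficientBeatsError(PwvloopError):
    """Fewer beats available than the requested group size."""


class DegenerateBeatError(PwvloopError):
    """Beat too short from onset to closing R-peak to build a loop."""


class NumericError(PwvloopError):
    """Non-finite value where a finite one is required."""


class NoEstimateError(PwvloopError):
    """All loops were flagged; no PWV estimate can be formed."""


class ManifestError(PwvloopError):
    """The input manifest is incomplete or inconsistent."""


class ConfigError(PwvloopError):
    """Unknown or invalid configuration key."""
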