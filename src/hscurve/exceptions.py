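"""Exception hierarchy for hscurve.

All package-specific failures derive from :class:`HscurveError` so callers
can catch one base class at pipeline boundaries.
"""


class HscurveError(Exception):
    """Base class for all hscurve errors."""


class DimensionError(HscurveError):
    """Array shapes are incompatible (cube vs. references, header vs. data)."""


class DegenerateReferenceError(HscurveError):
    """White and dark reference coincide somewhere; calibration denominator is zero."""


class DataQualityError(HscurveError):
    """Non-finite values where finite data is required."""


class FormatError(HscurveError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(HscurveError):
    """An ROI window or sweep grid does not fit inside the cube."""


class IdentifiabilityError(HscurveError):
    """Too few distinct abscissae to identify the quartic."""


class ConditioningError(HscurveError):
    """The weighted normal system is numerically singular."""


class GenerationError(HscurveError):
    """A synthetic profile failed its margin invariant after resampling."""
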