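"""Exception hierarchy shared across the package."""


class CofracError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CofracError, ValueError):
    """Invalid user-supplied parameter (rates, counts, thresholds)."""


class ConsistencyError(CofracError, ValueError):
    """Cross-referenced entities disagree (e.g. missing partner protein)."""


class DegenerateProfileError(CofracError, ValueError):
    """An operation received an all-zero or otherwise unusable profile."""


class ShapeError(CofracError, ValueError):
    """Input arrays have incompatible lengths or shapes."""


class NormalizationError(CofracError, ValueError):
    """A sample cannot be normalized (e.g. zero median)."""


class CalibrationError(CofracError, ValueError):
    """Molecular-weight calibration cannot be fitted or is ill-posed."""


class ValidationError(CofracError, ValueError):
    """File contents or data structures violate the documented contract."""


class UndefinedRateError(CofracError, ZeroDivisionError):
    """Interaction rate requested with an empty denominator group."""
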