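"""Exception hierarchy for ankledyn."""


class AnkledynError(Exception):
    """Base class for all ankledyn errors."""


class InvalidParameterError(AnkledynError, ValueError):
    """A scalar parameter is outside its admissible range."""


class InvalidModelError(AnkledynError, ValueError):
    """A subject/muscle model violates a structural constraint."""


class InvalidGeometryError(AnkledynError, ValueError):
    """Muscle-tendon geometry became unphysical (e.g. path shorter than tendon)."""


class DegenerateSegmentError(AnkledynError, ValueError):
    """Two path points coincide where a finite segment is required."""


class EmptySignalError(AnkledynError, ValueError):
    """A signal is too short to produce any output."""


class AlignmentError(AnkledynError, ValueError):
    """Two time series do not overlap or have mismatched lengths."""


class RangeError(AnkledynError, ValueError):
    """Interpolation outside the span of a series was requested."""


class ComparisonError(AnkledynError, ValueError):
    """A correlation/RMSE comparison is undefined for the given series."""


class InfeasibleTrialError(AnkledynError, ValueError):
    """The demanded joint moment exceeds the agonist group's capacity."""
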