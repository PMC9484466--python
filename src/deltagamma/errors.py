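"""Typed exceptions raised by the delta-gamma estimators."""


class DeltaGammaError(Exception):
    """Base class for all package-specific errors."""


class InsufficientPositivesError(DeltaGammaError):
    """Fewer than two positive observations: no spread can be estimated."""


class DegenerateSampleError(DeltaGammaError):
    """All positive observations are equal; the shape estimate diverges."""


class BoundaryCountError(DeltaGammaError):
    """A zero/positive count of 0 leaves one beta mixture component undefined."""


class PriorInapplicableError(DeltaGammaError):
    """The positive count is below the minimum the prior's posterior requires."""


class DataParseError(DeltaGammaError):
    """An input file contains a value that is not a nonnegative number."""
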