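"""Exception types shared across the pipeline."""


class SynscreenError(Exception):
    """Base class for all pipeline errors."""


class EmptySeriesError(SynscreenError):
    """Raised when blanking/log-transform leaves no usable points in a well."""


class InsufficientWindowError(SynscreenError):
    """Raised when a well has too few points inside the log2-OD fit window."""


class RatioUndefinedError(SynscreenError):
    """Raised when an MTX/DMSO slope ratio cannot be formed (no DMSO wells,
    or non-positive DMSO mean slope)."""


class ControlsDegenerateError(SynscreenError):
    """Raised when ratio_PC and ratio_NC are too close for the interaction
    score to be defined for an experiment."""


class PlacementError(SynscreenError):
    """Raised when a synthetic scene cannot place the requested objects
    without overlap within the retry budget."""


class MaskShapeError(SynscreenError):
    """Raised when masks or images of mismatched shapes are combined."""


class UndefinedRatioError(SynscreenError):
    """Raised when an intensity-ratio measure has an empty ROI or a
    zero-mean denominator."""
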