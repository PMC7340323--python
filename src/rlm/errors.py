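"""Exception types shared across the pipeline stages."""


class RLMError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RLMError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(RLMError, ValueError):
    """Source/detector geometry is inconsistent (e.g. source inside a slab)."""


class InsufficientDataError(RLMError, ValueError):
    """Not enough frames/points for the requested estimate."""


class PlacementFailureError(RLMError, RuntimeError):
    """Cell placement could not satisfy the minimum-separation constraint."""


class UndefinedRatioError(RLMError, ZeroDivisionError):
    """Sensitivity ratio requested with a zero denominator count."""


class FitFailureError(RLMError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


class FrameFormatError(RLMError, IOError):
    """A frame-stack file is malformed or truncated."""
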