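"""Exception hierarchy shared across the package."""


class MqeaslError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MqeaslError, ValueError):
    """An input violates a documented precondition or invariant."""


class DimensionMismatchError(ValidationError):
    """Two grids that must share shape/spacing do not."""


class DegenerateDesignError(MqeaslError, ValueError):
    """A regression design matrix is singular (e.g. all-equal predictor)."""


class FitError(MqeaslError, RuntimeError):
    """A model fit failed (no events, non-convergence, separation)."""


class NoCrossingError(MqeaslError, RuntimeError):
    """The fitted hazard-ratio curve never crosses 1 in the observed range."""

    def __init__(self, message, curve=None):
        super().__init__(message)
        self.curve = curve
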