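"""Exception hierarchy shared across the package."""


class GtenetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GtenetError, ValueError):
    """A supplied parameter is outside its admissible range."""


class ValidationError(GtenetError, ValueError):
    """A data structure violates one of its invariants."""


class ConvergenceError(GtenetError, RuntimeError):
    """An iterative procedure failed to reach its target.

    Attributes
    ----------
    best : float
        Best value achieved before giving up.
    """

    def __init__(self, message: str, best: float | None = None):
        super().__init__(message)
        self.best = best


class CalibrationError(GtenetError, RuntimeError):
    """Bisection bracket does not contain the calibration target."""


class IntegrationError(GtenetError, RuntimeError):
    """Numerical integration produced non-finite state."""
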