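"""Exception hierarchy shared across the package."""


class CardioemError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CardioemError, ValueError):
    """A physical or numerical parameter is outside its admissible range."""


class NumericDomainError(CardioemError, FloatingPointError):
    """A state or intermediate quantity left the numeric domain (NaN/Inf/overflow)."""


class DivergenceError(CardioemError, RuntimeError):
    """An explicit integration diverged; carries the step count where it blew up."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InsufficientDataError(CardioemError, ValueError):
    """Input traces are too short or too sparse for the requested analysis."""


class CalibrationError(CardioemError, RuntimeError):
    """Parameter calibration failed to reach the target residual."""
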