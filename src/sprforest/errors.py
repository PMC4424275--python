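"""Exception hierarchy shared across the package."""


class SprforestError(Exception):
    """Base class for all package errors."""


class DomainError(SprforestError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(SprforestError, ValueError):
    """Invalid parameter, scenario, design or experiment configuration."""


class InsufficientDataError(SprforestError, ValueError):
    """Too few observations for the requested estimate."""


class PairingError(SprforestError, ValueError):
    """Paired samples whose lengths do not match."""


class DesignError(SprforestError, ValueError):
    """A sampling design that cannot be realised (counts, plot types)."""


class DegenerateRegressionError(SprforestError, ValueError):
    """Regression update impossible (constant predictor)."""


class CalibrationError(SprforestError, RuntimeError):
    """Moment-matching calibration failed to converge.

    Carries the best residuals seen so the caller can judge how far off
    the search ended.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class SchemaError(SprforestError, ValueError):
    """A data file violates the expected schema."""
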