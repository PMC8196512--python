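"""Exception hierarchy shared across the package."""


class CanopykError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CanopykError):
    """A configuration value or structure is invalid."""


class ValidationError(CanopykError):
    """Data violates a dataset invariant."""


class DomainError(CanopykError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class MeasurementError(CanopykError):
    """Physically inconsistent measurement (e.g. below-canopy PAR above incident PAR)."""


class NumericError(CanopykError):
    """A numeric routine encountered non-finite values."""
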