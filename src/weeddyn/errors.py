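"""Exception hierarchy shared across the package."""


class WeeddynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WeeddynError):
    """A file does not conform to the expected layout (e.g. missing columns)."""


class ValidationError(WeeddynError):
    """Record-level content is invalid (bad codes, out-of-range values)."""


class DomainError(WeeddynError, ValueError):
    """A numeric argument is outside the mathematical domain of a function."""


class InfeasibleError(WeeddynError, ValueError):
    """The requested quantity does not exist for the given parameters."""


class InsufficientDataError(WeeddynError):
    """Not enough observations to fit the requested model."""


class CalibrationError(WeeddynError):
    """Calibration failed to bracket or converge; message carries diagnostics."""
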