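"""Exception hierarchy shared across the package."""


class SonomarkError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SonomarkError, ValueError):
    """A domain object or parameter violates its contract."""


class OutOfBoundsError(SonomarkError, ValueError):
    """A region or trajectory does not fit inside the grid it targets."""


class StabilityError(SonomarkError, ValueError):
    """An explicit time step violates the diffusion stability bound."""


class CalibrationError(SonomarkError, RuntimeError):
    """Source calibration could not be performed (zero response)."""


class DegenerateInputError(SonomarkError, ValueError):
    """An operation received an input with no usable content."""


class ConfigError(SonomarkError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
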