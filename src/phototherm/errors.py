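"""Exception types shared across the package."""


class PhotothermError(Exception):
    """Base class for package-specific errors."""


class InsufficientDataError(PhotothermError, ValueError):
    """A trace or plate does not contain enough samples for the requested fit."""


class CalibrationError(PhotothermError, ValueError):
    """A calibration produced a physically impossible value (e.g. zeta >= 1)."""


class ConfigError(PhotothermError, ValueError):
    """An invalid phantom / generator configuration."""


class StabilityError(PhotothermError, ValueError):
    """Explicit time step violates the finite-difference stability bound."""
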