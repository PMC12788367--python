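"""Exception hierarchy shared across the pipeline."""


class ThermoBreathError(Exception):
    """Base class for all package-specific errors."""


class MalformedFrameError(ThermoBreathError, ValueError):
    """Raw frame payload does not match the declared dimensions."""


class ConfigurationError(ThermoBreathError, ValueError):
    """A configuration value is outside its valid domain."""


class EncodingRangeError(ThermoBreathError, ValueError):
    """A temperature cannot be represented in the 16-bit radiometric format."""


class EmptyInputError(ThermoBreathError, ValueError):
    """An operation received an empty grid or sequence."""


class InvalidBoxError(ThermoBreathError, ValueError):
    """Bounding-box corners are inverted."""


class UsageError(ThermoBreathError, RuntimeError):
    """An operation was called in an invalid order (e.g. before initialization)."""


class NotReadyError(ThermoBreathError, RuntimeError):
    """Not enough samples buffered for the requested analysis."""


class OrderingError(ThermoBreathError, ValueError):
    """Samples arrived with non-monotone frame indices."""


class SceneError(ThermoBreathError, ValueError):
    """A synthetic scene violates its geometric invariants."""
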