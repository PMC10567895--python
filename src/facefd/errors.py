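"""Exception hierarchy shared across the package."""


class FaceFDError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(FaceFDError, ValueError):
    """Optical geometry is impossible (non-positive distance, object inside focus, ...)."""


class InvalidMeasurementError(FaceFDError, ValueError):
    """A landmark measurement is missing, non-positive or otherwise unusable."""


class PairingError(FaceFDError, ValueError):
    """Frontal/profile measurements cannot be paired (camera mismatch, missing view)."""


class ConfigError(FaceFDError, ValueError):
    """A configuration file or value is invalid."""


class SchemaError(FaceFDError, ValueError):
    """A tabular input violates the required column schema."""
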