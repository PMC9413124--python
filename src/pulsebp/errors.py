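"""Exception hierarchy shared by all pulsebp modules."""


class PulseBPError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PulseBPError, ValueError):
    """A physical quantity violates its precondition (non-positive length, etc.)."""


class CalibrationError(PulseBPError):
    """Calibration could not be performed (degenerate or insufficient data)."""


class ConfigError(PulseBPError):
    """A configuration value is infeasible for the requested operation."""


class DataError(PulseBPError):
    """Measured data violates an assumption (non-positive intensity, ...)."""


class FormatError(PulseBPError):
    """A session file does not match the documented dialect."""


class MeasurementQualityError(PulseBPError):
    """Too few usable beats / pairs to produce a measurement."""


class SimulationError(PulseBPError):
    """Forward-model input outside the validity region of the simulator."""


class UsageError(PulseBPError):
    """API misuse, e.g. applying a calibration to the wrong subject."""
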