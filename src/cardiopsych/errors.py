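"""Exception hierarchy shared across the package."""


class CardiopsychError(Exception):
    """Base class for all package errors."""


class ParameterError(CardiopsychError, ValueError):
    """Invalid specification or configuration value."""


class InsufficientDataError(CardiopsychError, ValueError):
    """Too few observations for the requested computation."""


class DetectionError(CardiopsychError, RuntimeError):
    """R-peak detection failed (flat, too-short or missing signal)."""


class DelineationError(CardiopsychError, RuntimeError):
    """Wave delineation failed."""


class MeasurementError(CardiopsychError, KeyError):
    """A requested lead or measurement is unavailable."""


class UndefinedCorrelationError(CardiopsychError, ValueError):
    """Correlation undefined (constant input)."""


class AlignmentError(CardiopsychError, ValueError):
    """Feature and target tables share no usable subjects."""


class StructuralError(CardiopsychError, ValueError):
    """Malformed score hierarchy or norm table."""


class ConfigurationError(CardiopsychError, ValueError):
    """Invalid run configuration."""
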