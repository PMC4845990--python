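"""Exception hierarchy for the TEB elongation pipeline."""


class TEBError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(TEBError):
    """A physical measurement is negative or otherwise impossible."""


class SchemaError(TEBError):
    """Region / shape / cell records are mutually inconsistent."""


class EstimationError(TEBError):
    """A kinetic quantity cannot be estimated from the supplied time course."""


class ConfigError(TEBError):
    """A model variant was requested without the parameters it needs."""


class DataError(TEBError):
    """An input table violates its declared invariants."""


class GeometryError(TEBError):
    """A path-geometry quantity is outside its admissible range."""


class FluxError(TEBError):
    """A flux computation is degenerate (e.g. zero donor production)."""
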