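"""Exception hierarchy shared across the package."""


class AdsorbkitError(ValueError):
    """Base class for all domain validation errors."""


class DegenerateColumnError(AdsorbkitError):
    """The tracer and exclusion anchors coincide (vt == v0): Kd undefined."""


class InconsistentVolumesError(AdsorbkitError):
    """Column volumes violate 0 < v0 < vt <= vb."""


class KdRangeError(AdsorbkitError):
    """A raw distribution coefficient lies too far outside [0, 1]."""


class SchemaError(AdsorbkitError):
    """A delimited-text input does not match the expected schema."""
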