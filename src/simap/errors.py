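"""Exception hierarchy shared across the package."""


class SimapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SimapError, ValueError):
    """A configuration value is out of range or inconsistent."""


class LayoutError(SimapError, ValueError):
    """A plate layout is malformed or does not fit the plate density."""


class SchemaError(SimapError, ValueError):
    """A data table violates its declared schema."""


class DegenerateSentinelError(SimapError, ValueError):
    """The sentinel has no usable dynamic range (denominator ~ 0)."""
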