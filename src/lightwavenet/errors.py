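"""Exception types shared across the package."""


class LightWaveNetError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(LightWaveNetError, ValueError):
    """An array has an incompatible or unsupported shape."""


class ConfigError(LightWaveNetError, ValueError):
    """A configuration value is invalid or internally inconsistent."""


class DataError(LightWaveNetError, ValueError):
    """A dataset or split is empty, missing, or malformed."""


class UsageError(LightWaveNetError, RuntimeError):
    """An API was called in a way its contract forbids."""
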