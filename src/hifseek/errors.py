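"""Exception hierarchy shared across the package."""


class HifseekError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HifseekError, ValueError):
    """Invalid simulation or run configuration."""


class DataError(HifseekError, ValueError):
    """Malformed or inconsistent input data."""
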