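"""Exception types shared across the package."""


class PeriobiomeError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(PeriobiomeError):
    """A table file or in-memory table violates its format contract."""


class ConfigError(PeriobiomeError):
    """Invalid configuration value, study design, or effect specification."""
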