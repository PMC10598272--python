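"""Exception types shared across the package."""


class FreezecalcError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FreezecalcError, ValueError):
    """Invalid generator or pipeline configuration."""


class AlignmentError(FreezecalcError, ValueError):
    """Time series that must share a frame clock do not."""


class DegenerateTraceError(FreezecalcError, ValueError):
    """A trace is constant / zero-variance where variability is required."""


class SchemaError(FreezecalcError, RuntimeError):
    """An on-disk session container does not match the expected schema."""
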