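"""Exception hierarchy shared across the package."""


class SonomtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SonomtlError, ValueError):
    """An invalid configuration value (probability out of range, unknown task, ...)."""


class GenerationError(SonomtlError, RuntimeError):
    """Synthetic image generation failed (lesion outside image bounds, ...)."""


class DataError(SonomtlError, ValueError):
    """A dataset violates the label or geometry invariants."""


class SplitError(SonomtlError, ValueError):
    """Patient-level splitting is impossible (too few patients, ...)."""
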