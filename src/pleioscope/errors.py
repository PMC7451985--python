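"""Exception types shared across the pipeline."""


class PleioscopeError(Exception):
    """Base class for all package errors."""


class ConfigError(PleioscopeError):
    """Invalid simulation or pipeline configuration (e.g. non-PSD correlation)."""


class MapError(PleioscopeError):
    """Invalid genetic map (non-increasing or negative marker positions)."""


class ValidationError(PleioscopeError):
    """Malformed input table or unmet statistical precondition."""
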