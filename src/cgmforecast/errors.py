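"""Exception types shared across the package."""

__all__ = ["ValidationError", "DataError"]


class ValidationError(ValueError):
    """A parameter, configuration value, or argument violates its contract."""


class DataError(ValueError):
    """Input data are malformed or insufficient for the requested operation."""
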