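"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a run configuration or strategy request is invalid."""


class InputError(ValueError):
    """Raised when data handed to an operation violates its contract."""
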