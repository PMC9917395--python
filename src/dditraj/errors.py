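"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""
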