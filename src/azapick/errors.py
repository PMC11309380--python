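"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value (bad correlation matrix, unknown model id, ...)."""


class InvalidArgumentError(ValueError):
    """An invalid runtime argument (bad sample count, mismatched lengths, ...)."""
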