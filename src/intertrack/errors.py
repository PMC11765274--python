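"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration: unknown species, unbalanced channel, bad grid, ..."""
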