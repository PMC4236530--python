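"""Package-level exception types."""


class ConfigError(ValueError):
    """Invalid configuration (bad rates, unordered dates, unknown keys)."""


class DataError(ValueError):
    """Input data violates the expected schema or coverage contracts."""
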