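"""Exception types shared across the package."""


class PoolscanError(Exception):
    """Base class for all package errors."""


class ConfigError(PoolscanError, ValueError):
    """A configuration value violates an invariant; message names the field."""


class ParseError(PoolscanError, ValueError):
    """Malformed input text (mpileup, sync, genotype tables)."""


class GenerationError(PoolscanError, ValueError):
    """A simulator could not honour its configuration."""
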