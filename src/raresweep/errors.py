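"""Exception types shared across the package."""


class RaresweepError(Exception):
    """Base class for package errors."""


class ConfigError(RaresweepError, ValueError):
    """A configuration object violates its invariants."""


class DataError(RaresweepError, ValueError):
    """An input value is outside its valid domain (e.g. a frequency > 1)."""
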