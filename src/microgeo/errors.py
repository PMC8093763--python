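"""Exception types shared across the package."""


class MicrogeoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MicrogeoError):
    """Invalid configuration (bad dimensions, inconsistent parameters)."""


class ParseError(MicrogeoError):
    """Malformed input file; the message names the offending row/column."""


class EmptyResultError(MicrogeoError):
    """An operation removed everything (e.g. all taxa filtered out)."""


class UndefinedMetricError(MicrogeoError):
    """A performance measure is mathematically undefined for this input."""
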