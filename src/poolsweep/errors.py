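"""Exception hierarchy shared across the package."""


class PoolsweepError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PoolsweepError, ValueError):
    """A configuration value violates its documented invariant."""


class ParseError(PoolsweepError, ValueError):
    """An input file could not be parsed; the message names the offending line."""


class FormatError(PoolsweepError, ValueError):
    """An input file lacks a required field or annotation."""


class OrderingError(PoolsweepError, ValueError):
    """Records were not sorted by (chromosome, position) where required."""


class DegenerateError(PoolsweepError, ValueError):
    """A statistic is undefined on the given input (e.g. zero variance)."""
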