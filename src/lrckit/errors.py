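"""Exception types shared across the toolkit."""


class ConfigError(ValueError):
    """A configuration block is internally inconsistent or out of range."""


class InputError(ValueError):
    """An input table/point set does not satisfy an operation's preconditions."""


class GenerationError(RuntimeError):
    """A synthetic-data generator cannot realize the requested targets."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero denominator)."""
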