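"""Exception hierarchy."""


class PolyhomeoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PolyhomeoError, ValueError):
    """A parameter or configuration value is outside its valid domain."""


class ValidationError(PolyhomeoError, ValueError):
    """An input file or in-memory object violates its contract."""


class UndefinedStatisticError(PolyhomeoError, ArithmeticError):
    """A requested statistic is undefined for the given input (e.g. zero total)."""
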