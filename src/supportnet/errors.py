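"""Exception hierarchy for supportnet."""


class SupportNetError(Exception):
    """Base class for all supportnet errors."""


class CorpusFormatError(SupportNetError):
    """A corpus file is malformed (missing field, bad format)."""


class EmptyInputError(SupportNetError):
    """An operation received an empty corpus/network where content is required."""


class UndefinedStatisticError(SupportNetError):
    """A statistic is undefined for the given input (e.g. ASPL of isolated nodes)."""


class ConfigError(SupportNetError):
    """Invalid configuration values."""


class UsageError(SupportNetError):
    """Caller misuse (unknown format, override naming a nonexistent module)."""
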