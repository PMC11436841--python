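"""Exception hierarchy shared by all pipeline stages."""


class SyncflowError(Exception):
    """Base class for all syncflow errors."""


class InvalidArgumentError(SyncflowError, ValueError):
    """An argument violates an operation's precondition."""


class UndefinedStatisticError(SyncflowError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class FormatError(SyncflowError, ValueError):
    """An input file does not conform to the expected on-disk format."""
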