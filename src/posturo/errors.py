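"""Exception hierarchy shared across the toolkit.

Every error raised on purpose derives from :class:`PosturoError` so callers
(and the CLI) can distinguish expected failure modes from bugs.
"""


class PosturoError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PosturoError):
    """Malformed input data: bad CSV cells, non-monotone timestamps, ..."""


class ParameterError(PosturoError, ValueError):
    """A parameter violates its documented domain."""


class DomainError(PosturoError):
    """A value is outside its physical domain (e.g. COP off the board)."""


class TooShortError(PosturoError):
    """Signal too short for the requested operation."""


class UnrecoverableSignalError(PosturoError):
    """No usable samples remain after validity screening."""


class GroupingError(PosturoError):
    """Records that must share grouping keys do not."""


class PairingError(PosturoError):
    """Paired vectors have mismatched lengths or too few pairs."""


class UndefinedICCError(PosturoError):
    """ICC is undefined (zero total variance)."""


class DesignError(PosturoError):
    """A study design or comparison references unknown labels."""
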