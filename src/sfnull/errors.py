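"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`SFNullError`
so callers can catch one type at pipeline boundaries.
"""


class SFNullError(Exception):
    """Base class for all errors raised by sfnull."""


class FormatError(SFNullError):
    """A delimited-text file does not have the expected shape or columns."""


class ParseError(SFNullError):
    """A field could not be parsed (reports the offending row)."""


class ValidationError(SFNullError):
    """An in-memory object violates a domain invariant."""


class AlignmentError(SFNullError):
    """Sample ids of an expression matrix cannot be aligned to a sample table."""


class ConfigurationError(SFNullError):
    """A run configuration is internally inconsistent or infeasible."""


class DegenerateInputError(SFNullError):
    """An input is degenerate for the requested statistic (constant vector,
    empty eligible edge set, duplicate coordinates under inverse-distance
    weighting, ...)."""


class PackingError(SFNullError):
    """Non-overlapping cluster centers could not be placed within the
    proposal budget."""

    def __init__(self, message: str, placed: int = 0, requested: int = 0):
        super().__init__(message)
        self.placed = placed
        self.requested = requested
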