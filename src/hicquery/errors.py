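"""Exception hierarchy.

Data problems (bad files, out-of-range coordinates) raise :class:`DataError`
subclasses; bad command-line usage raises :class:`UsageError`.  The CLI maps
these onto exit codes 1 and 2 respectively.
"""


class HicQueryError(Exception):
    """Base class for all errors raised by this package."""


class DataError(HicQueryError):
    """Input data is malformed, inconsistent, or out of range."""


class ParseError(DataError):
    """A line of an input file could not be parsed; message names the line."""


class ValidationError(DataError):
    """Parsed data violates an invariant (overlapping bins, negative counts...)."""


class FormatError(DataError):
    """A binary cache file has the wrong magic string or version."""


class QueryError(DataError):
    """A query cannot be answered (empty bin set, unknown chromosome...)."""


class UsageError(HicQueryError):
    """Invalid combination of command-line options."""
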