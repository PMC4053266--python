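"""Exception hierarchy shared across the package.

Each subclass maps to a distinct CLI exit code (see :mod:`mcia.cli`).
"""


class MciaError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InvalidArgumentError(MciaError):
    """A parameter value violates its contract (e.g. non-positive fill value)."""

    exit_code = 2


class TableFormatError(MciaError):
    """An input file is unreadable or mis-shapen."""

    exit_code = 3


class DataDomainError(MciaError):
    """Values violate a mathematical precondition (negatives, zero sums, log of 0)."""

    exit_code = 4


class RankError(MciaError):
    """More axes requested than the data can support, or no variance left."""

    exit_code = 5


class AlignmentError(MciaError):
    """Sample identifiers cannot be reconciled across tables."""

    exit_code = 6
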