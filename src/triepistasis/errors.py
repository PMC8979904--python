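"""Exception hierarchy.

Every error raised by the package derives from :class:`TriepistasisError`
so callers (and the CLI) can distinguish package failures from bugs.
"""


class TriepistasisError(Exception):
    """Base class for all package errors."""


class ParseError(TriepistasisError):
    """A table file could not be parsed; message names the file and row."""


class AlignmentError(TriepistasisError):
    """Line or marker identifiers disagree between input files."""


class CodingError(TriepistasisError):
    """A genotype value outside the {-1, +1, missing} coding was found."""


class DomainError(TriepistasisError, ValueError):
    """A numeric argument fell outside its mathematical domain."""


class DegenerateInputError(TriepistasisError):
    """Input is formally valid but carries no information (e.g. constant trait)."""


class ConfigurationError(TriepistasisError):
    """A user-supplied parameter is inconsistent with the data."""


class RankError(TriepistasisError):
    """The design has more columns than observations even after capping."""
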