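"""Exception hierarchy for haplotrace.

All errors raised by the library derive from :class:`HaplotraceError` so a
pipeline driver can catch one base class; each subclass also derives from
``ValueError`` because every condition is a malformed or inconsistent input.
"""


class HaplotraceError(Exception):
    """Base class for all haplotrace-specific errors."""


class AlignmentShapeError(HaplotraceError, ValueError):
    """Sequences in an alignment do not all share the same length."""


class DuplicateIdError(HaplotraceError, ValueError):
    """A specimen or haplotype identifier occurs more than once."""


class EmptyInputError(HaplotraceError, ValueError):
    """An input file or collection contains no records."""


class EmptyResultError(HaplotraceError, ValueError):
    """A filtering step removed every record."""


class BoundsError(HaplotraceError, ValueError):
    """A coordinate window or threshold is outside its valid range."""


class MetadataError(HaplotraceError, ValueError):
    """A specimen table is missing required columns or holds invalid values."""


class JoinError(HaplotraceError, ValueError):
    """Alignment and specimen metadata do not cover the same specimens."""


class AmbiguityError(HaplotraceError, ValueError):
    """Ambiguous bases present where only unambiguous A/C/G/T are allowed."""


class UndefinedStatisticError(HaplotraceError, ValueError):
    """A statistic was requested for a sample too small to define it."""


class CapacityError(HaplotraceError, ValueError):
    """A simulation requires more mutable sites than the sequence provides."""
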