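"""Typed errors raised by the bestgate pipeline.

Every error that a CLI command can surface as a one-line diagnostic derives
from :class:`BestgateError`, so callers can catch one base class.
"""


class BestgateError(Exception):
    """Base class for all bestgate errors."""


# --- structure I/O ---------------------------------------------------------

class FormatError(BestgateError):
    """A coordinate file (or field) does not parse under the named standard."""


class EmptyStructureError(BestgateError):
    """A coordinate file parsed but contains no atoms."""


class IncompleteRingError(BestgateError):
    """A constriction residue is absent from one or more chains."""


class MissingAtomError(BestgateError):
    """The atom required by the ring-selection rule is not in the residue."""


class AmbiguousChainsError(BestgateError):
    """More than five chains carry the residue; an explicit chain list is needed."""


# --- geometry --------------------------------------------------------------

class GeometryError(BestgateError):
    """Degenerate geometry (e.g. coincident ring points)."""


class InsufficientOverlapError(BestgateError):
    """Fewer than three matched atoms between two structures."""


# --- electrophysiology -----------------------------------------------------

class ProtocolError(BestgateError):
    """Recording does not match the declared step protocol."""


class NoReversalError(BestgateError):
    """Current does not change sign over the voltage range."""


class WindowError(BestgateError):
    """Fewer than two I-V points fall inside a slope-conductance window."""


class UndefinedFoldError(BestgateError):
    """Fold stimulation is undefined (zero denominator current)."""
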