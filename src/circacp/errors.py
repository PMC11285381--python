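"""Exception hierarchy.

Contract violations (bad arguments, broken preconditions) raise
:class:`ContractError`; data-dependent failures raise the more specific
subclasses so callers can distinguish "you called me wrong" from "this
subject's data cannot be processed".
"""


class CircaCPError(Exception):
    """Base class for all package errors."""


class ContractError(CircaCPError):
    """A documented precondition was violated by the caller."""


class ParseError(CircaCPError):
    """A file could not be parsed; the message names the offending row."""


class GapError(CircaCPError):
    """The epoch grid has holes; ``intervals`` lists the missing spans."""

    def __init__(self, message, intervals=None):
        super().__init__(message)
        self.intervals = intervals or []


class FitError(CircaCPError):
    """Iterative model fitting failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateError(CircaCPError):
    """Input is degenerate for the requested estimator (e.g. zero variance)."""


class DegenerateRhythmError(CircaCPError):
    """The fitted circadian curve is flat; no day/night split exists."""


class NoRhythmError(CircaCPError):
    """No circadian transitions were found for a subject."""


class NoEventsError(CircaCPError):
    """All candidate search windows were dropped; no events to report."""


class WindowTooShortError(CircaCPError):
    """A change-point window is shorter than twice the minimum segment."""
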