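"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`GaitError`
so callers can catch domain failures without swallowing programming errors.
"""


class GaitError(Exception):
    """Base class for all gaittool errors."""


class TraceFormatError(GaitError, ValueError):
    """A trace or gates file is malformed (missing column, bad event label...)."""


class SamplingError(GaitError, ValueError):
    """The time base is not uniform at the declared sample rate.

    Attributes
    ----------
    index : int
        Index of the first sample pair violating the uniformity tolerance.
    """

    def __init__(self, message: str, index: int = -1):
        super().__init__(message)
        self.index = index


class GateOrderError(GaitError, ValueError):
    """Gate events are inconsistent (end before start, duplicates...)."""


class WindowError(GaitError, ValueError):
    """The analysis window falls outside the trace or is too short."""


class InsufficientStepsError(GaitError, ValueError):
    """Fewer than two foot contacts detected; step timing is undefined."""


class DomainError(GaitError, ValueError):
    """A quantity is outside its mathematical domain (zero time, ICC > 1...)."""
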