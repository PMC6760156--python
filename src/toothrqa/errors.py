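"""Exception hierarchy shared across the pipeline stages."""


class ToothRQAError(Exception):
    """Base class for all package errors."""


class ValidationError(ToothRQAError, ValueError):
    """A parameter or input violates a documented invariant.

    ``field`` names the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class InsufficientLengthError(ToothRQAError, ValueError):
    """A time-series is too short for the requested embedding.

    ``required`` carries the minimum usable number of samples.
    """

    def __init__(self, message: str, required: int):
        super().__init__(message)
        self.required = required


class DegenerateTrajectoryError(ToothRQAError, ValueError):
    """All pairwise distances vanish (constant trajectory) or a series
    has zero variance, so no recurrence radius can be calibrated."""


class DisjointSupportsError(ToothRQAError, ValueError):
    """Two series share no overlapping time interval."""


class InsufficientDataError(ToothRQAError, ValueError):
    """Too few non-missing observations for the requested statistic."""


class InestimableContrastError(ToothRQAError, ValueError):
    """The requested group contrast cannot be estimated (constant
    response, a single diagnosis class, or an emptied class)."""


class FileFormatError(ToothRQAError, ValueError):
    """A CSV input violates the expected format.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
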