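"""Exception hierarchy for the pcqm package.

All errors raised by pcqm derive from :class:`PCQMError`, so callers can
catch the whole family with a single except clause while the subclasses
also inherit from the closest builtin (``ValueError`` / ``RuntimeError``)
for idiomatic handling.
"""


class PCQMError(Exception):
    """Base class for all pcqm errors."""


class InvalidSpecError(PCQMError, ValueError):
    """A pattern / sampling specification violates its preconditions."""


class PackingFailureError(PCQMError, RuntimeError):
    """Sequential-inhibition placement could not fit the requested points.

    Attributes
    ----------
    attempts : int
        Total proposals made before giving up.
    placed : int
        Points successfully placed.
    """

    def __init__(self, message: str, attempts: int, placed: int):
        super().__init__(message)
        self.attempts = attempts
        self.placed = placed


class InsufficientPointsError(PCQMError, ValueError):
    """An operation needs more points than the pattern contains."""


class PatternCSVError(PCQMError, ValueError):
    """A stem-map CSV could not be parsed; ``row`` is the 1-based file line."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class VacantQuadrantError(PCQMError, RuntimeError):
    """A quadrant holds fewer trees than the requested order.

    Attributes identify the offending sample point (index and coordinates)
    and the quadrant (0-based, counter-clockwise from the +x axis).
    """

    def __init__(self, message: str, point_index: int, quadrant: int):
        super().__init__(message)
        self.point_index = point_index
        self.quadrant = quadrant


class SamplingFailureError(PCQMError, RuntimeError):
    """The redraw budget was exhausted before N valid sample points were found."""

    def __init__(self, message: str, n_valid: int):
        super().__init__(message)
        self.n_valid = n_valid


class DegenerateSampleError(PCQMError, ValueError):
    """All quadrant distances are zero; the density estimate is undefined."""


class InvalidTrueDensityError(PCQMError, ValueError):
    """A relative error metric was asked for with a non-positive true density."""


class ResultsCSVError(PCQMError, ValueError):
    """A simulation-results CSV could not be parsed; ``row`` is the file line."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
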