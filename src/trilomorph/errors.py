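"""Exception hierarchy.

All errors raised by the package derive from :class:`TrilomorphError` so callers
can catch the package's failures with a single except clause.
"""


class TrilomorphError(Exception):
    """Base class for all package errors."""


class ParseError(TrilomorphError):
    """A text input could not be parsed (bad field, no data lines...)."""


class FormatError(TrilomorphError):
    """A structured file (ESRI ASCII grid, TPS record) violates its format."""


class CardinalityError(FormatError):
    """A landmark record does not carry exactly the expected landmark count."""


class DegenerateGeometryError(TrilomorphError):
    """Input geometry is degenerate (collinear cloud, zero-size configuration)."""


class EmptyRasterError(TrilomorphError):
    """A DEM holds no valid (non-nodata) cell."""


class EmptyProfileError(TrilomorphError):
    """A profile line crosses only nodata cells."""


class BoundsError(TrilomorphError):
    """A requested coordinate or window falls outside the available extent."""


class InsufficientReliefError(TrilomorphError):
    """Too few lobes/furrows can be resolved on a profile (effaced relief).

    Carries ``n_maxima`` and ``n_minima`` actually found so callers can report
    the preservation state (e.g. "only one transglabellar furrow resolved").
    """

    def __init__(self, message: str, n_maxima: int = 0, n_minima: int = 0):
        super().__init__(message)
        self.n_maxima = n_maxima
        self.n_minima = n_minima


class ConvergenceError(TrilomorphError):
    """Iterative superimposition failed to converge; carries the last change norm."""

    def __init__(self, message: str, last_change: float):
        super().__init__(message)
        self.last_change = last_change


class SampleSizeError(TrilomorphError):
    """Too few specimens or too-small groups for the requested statistic."""


class PipelineError(TrilomorphError):
    """A pipeline stage failed; carries the stage name and offending specimen."""

    def __init__(self, stage: str, message: str, specimen_id: str | None = None):
        super().__init__(f"stage '{stage}': {message}"
                         + (f" (specimen {specimen_id})" if specimen_id else ""))
        self.stage = stage
        self.specimen_id = specimen_id
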