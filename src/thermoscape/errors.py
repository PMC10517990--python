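"""Exception hierarchy for thermoscape.

Every error raised by the library derives from :class:`ThermoscapeError`
so callers can catch domain failures without masking programming errors.
"""


class ThermoscapeError(Exception):
    """Base class for all thermoscape errors."""


class InvalidMeasurementError(ThermoscapeError):
    """A raw measurement is physically impossible (non-positive time, etc.)."""


class ExcludedTrialError(ThermoscapeError):
    """The trial was flagged invalid (animal refused / uncooperative)."""


class InsufficientDataError(ThermoscapeError):
    """Too few retained observations to compute the requested statistic."""


class OrderingError(ThermoscapeError):
    """Paired thermal limits are in the wrong order (CTgape <= CTmin)."""


class UndefinedIntervalError(ThermoscapeError):
    """Q10 requested over a zero-width temperature interval."""


class AnchorError(ThermoscapeError):
    """Zero-velocity anchors do not bracket the observed temperatures."""


class UnderdeterminedFitError(ThermoscapeError):
    """Fewer than three distinct temperatures supplied to the curve fit."""


class UnsupportedLatitudeError(ThermoscapeError):
    """Latitude within the polar circles; no polar day/night handling."""


class SequencingError(ThermoscapeError):
    """Daily weather records are not on consecutive calendar dates."""


class ContiguityError(ThermoscapeError):
    """An hourly series has gaps where contiguous time is required."""


class DegenerateRangeError(ThermoscapeError):
    """Min-max normalization of an all-equal collection."""


class CoverageError(ThermoscapeError):
    """Daily weather stack does not cover all dates of a season window."""


class AlignmentError(ThermoscapeError):
    """Input grids are not on an identical georeference."""


class OutOfExtentError(ThermoscapeError):
    """A presence point falls outside the raster bounds."""


class InfeasibleRuleError(ThermoscapeError):
    """No grid cell satisfies the presence-sampling rule."""
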