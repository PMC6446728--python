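"""Exception hierarchy.

Every failure mode the library promises to detect raises a distinct, named
exception so callers (and the CLI's exit-code mapping) can react precisely.
``LeukotrackError`` is the common base; ``ConfigError`` marks problems with
user configuration rather than with the data itself.
"""


class LeukotrackError(Exception):
    """Base class for all leukotrack errors."""


class ConfigError(LeukotrackError):
    """Invalid or inconsistent analysis configuration."""


class TrackParseError(LeukotrackError):
    """Base class for track-table parsing failures."""


class MissingColumnError(TrackParseError):
    """A required column is absent from the input table."""


class DuplicateTimepointError(TrackParseError):
    """The same (track id, time) appears more than once — broken export."""


class NonNumericCoordinateError(TrackParseError):
    """A time or coordinate cell could not be parsed as a number."""


class EmptyTrackSetError(LeukotrackError):
    """An operation requiring at least one track received none."""


class TrackTooShortError(LeukotrackError):
    """A per-track statistic needs more points than the track has."""


class TimeGridError(LeukotrackError):
    """Track times do not align to a multiple of the frame interval."""


class InvalidParameterError(LeukotrackError, ValueError):
    """A numeric parameter is outside its legal range."""


class InsufficientDataError(LeukotrackError):
    """Too few observations (lags, values, pairs) for the computation."""


class DegenerateVarianceError(LeukotrackError):
    """A test statistic is undefined because the variance is zero."""


class MetricNotFoundError(LeukotrackError, KeyError):
    """The requested per-track metric is not a column of the stats table."""
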