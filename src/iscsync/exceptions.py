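"""Exception hierarchy for iscsync.

All package-specific failures derive from :class:`IscsyncError` so callers
can catch everything from this library with one clause.
"""


class IscsyncError(Exception):
    """Base class for all iscsync errors."""


class DataFormatError(IscsyncError, ValueError):
    """A file or table does not conform to the expected layout."""


class ScheduleError(IscsyncError, ValueError):
    """A segment schedule is inconsistent (overlaps, out of bounds, ...)."""


class EmptySelectionError(IscsyncError, KeyError):
    """A segment selection matched no schedule entries."""


class DimensionError(IscsyncError, ValueError):
    """Array shapes are incompatible."""


class FilterConfigError(IscsyncError, ValueError):
    """A band-pass specification is invalid for the sampling rate."""


class SeriesLengthError(IscsyncError, ValueError):
    """A time series is too short for the requested operation."""


class DegenerateInputError(IscsyncError, ValueError):
    """Input has no variance where a statistic requires it."""


class AlignmentError(IscsyncError, ValueError):
    """Identifiers of two objects that must be aligned do not match."""


class ConfigError(IscsyncError, ValueError):
    """An inference or simulation configuration is invalid."""
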