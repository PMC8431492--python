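"""Exception hierarchy for skelquant.

Every error raised deliberately by the package derives from
:class:`SkelQuantError`, so callers (and the CLI) can catch one base class.
"""


class SkelQuantError(Exception):
    """Base class for all skelquant errors."""


class KeypointFormatError(SkelQuantError):
    """Malformed keypoint input (bad JSON, wrong array length, missing columns)."""


class InputError(SkelQuantError):
    """Invalid input at the operation boundary (empty directory, wrong series count)."""


class UnusableRecordingError(SkelQuantError):
    """No frame (or too few frames) with all required joints detected."""


class DegenerateSegmentError(SkelQuantError):
    """Two coincident joints: the segment angle is undefined."""


class SeriesTooShortError(SkelQuantError):
    """A time series is shorter than the operation's minimum length."""


class UndefinedACFError(SkelQuantError):
    """Autocorrelation undefined because a sub-series has zero variance."""


class DegenerateVarianceError(SkelQuantError):
    """Paired differences are identical and nonzero: the t statistic diverges."""


class InsufficientPairsError(SkelQuantError):
    """Fewer than two complete before/after pairs remain for a column."""


class SubjectMismatchError(SkelQuantError):
    """Before/after cohorts do not contain the same subjects."""


class ConfigError(SkelQuantError):
    """Invalid configuration value."""
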