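"""Exception hierarchy.

All package errors derive from :class:`TopoquantError` so callers can catch one
base class; the CLI maps the three branches (config / data / numerical) to
distinct exit codes.
"""


class TopoquantError(Exception):
    """Base class for all errors raised by topoquant."""


class ConfigError(TopoquantError):
    """Invalid or incomplete run/scenario configuration."""


class InvalidParameterError(TopoquantError, ValueError):
    """A parameter is outside its documented domain."""


class GeometryError(TopoquantError):
    """A band falls outside the rendered profile."""


class BoundsError(TopoquantError):
    """Region of interest outside the image."""


class AmbiguousLadderError(TopoquantError):
    """Two detected peaks map to the same linking-number index."""


class NoBandsError(TopoquantError):
    """A band table with no bands where at least one is required."""


class InvalidBandError(TopoquantError):
    """A band with nonpositive integrated intensity."""


class DegenerateReferenceError(TopoquantError):
    """RSU reference lanes are not separated in weighted Lk."""


class InvalidDurationError(TopoquantError, ValueError):
    """Nonpositive time interval for an activity."""


class DegenerateBaselineError(TopoquantError):
    """Zero baseline activity in a relative-activity computation."""


class InsufficientReplicatesError(TopoquantError):
    """A group has fewer observations than the method requires."""


class InvalidDesignError(TopoquantError):
    """Fewer than two groups supplied to a group comparison."""


class CalibrationError(TopoquantError):
    """Standard curve cannot be fitted (too few points or nonpositive slope)."""


class ParseError(TopoquantError):
    """Malformed value in an input table; the message names the offending row."""


class DuplicateRecordError(TopoquantError):
    """Duplicate gene within a pathway in an expression table."""
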