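"""Exception hierarchy for screensift.

Every error raised on a user-facing path derives from :class:`ScreenSiftError`
so callers (and the CLI) can catch one base class.
"""


class ScreenSiftError(Exception):
    """Base class for all screensift errors."""


class SchemaError(ScreenSiftError):
    """A tabular input violates its documented schema (bad header, duplicate
    well, invalid role, non-numeric field...)."""


class ParseError(SchemaError):
    """A cell could not be parsed; message carries the offending line."""


class CrossReferenceError(ScreenSiftError):
    """A record references an identifier that does not exist elsewhere in the
    bundle (unknown well, unknown pool)."""


class ConfigError(ScreenSiftError):
    """Invalid or incomplete configuration (missing column mapping, bad
    thresholds, class proportions that do not sum to one...)."""


class EmptyInputError(ScreenSiftError):
    """An input table contained zero usable rows."""


class DegeneratePlateError(ScreenSiftError):
    """A plate cannot be normalized (no sample wells, or nonpositive sample
    median)."""


class ZeroDispersionError(ScreenSiftError):
    """The MAD of the values being scored is zero; a robust Z is undefined."""


class InsufficientDataError(ScreenSiftError):
    """Fewer data points than the operation requires."""


class AlignmentError(ScreenSiftError):
    """Two series that must share a time grid do not."""


class DomainError(ScreenSiftError):
    """A value lies outside the mathematical domain of the operation
    (nonpositive abundance passed to a log-space fit, negative fold...)."""


class StateError(ScreenSiftError):
    """An operation was invoked on an object in the wrong state."""
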