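"""Exception hierarchy for the tapjid pipeline.

Every stage raises a subclass of :class:`TapjidError` so callers can catch
pipeline failures without masking programming errors.
"""


class TapjidError(Exception):
    """Base class for all tapjid errors."""


class ConfigurationError(TapjidError):
    """Invalid configuration value (bad condition tag, out-of-range index, ...)."""


class ParseError(TapjidError):
    """Malformed on-disk input; message carries file path and line number."""


class EmptyInputError(TapjidError):
    """An operation received no data where at least one record is required."""


class FormatError(TapjidError):
    """A structured file violates its declared format (missing header, grid mismatch)."""


class IncompatibilityError(TapjidError):
    """Two objects that must share a grid/normalization do not."""


class DomainError(TapjidError):
    """A value lies outside the mathematical domain of an operation (e.g. ITI <= 0)."""


class InferenceError(TapjidError):
    """A statistical routine was called with groups too small or a design it cannot test."""


class DesignError(TapjidError):
    """A study design is inconsistent with the data (empty period, missing baseline days)."""
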