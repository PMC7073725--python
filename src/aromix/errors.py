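"""Exception hierarchy for aromix.

All package-specific errors derive from :class:`AromixError` so callers can
catch one base class at pipeline level while tests assert on the specific
subclass.
"""


class AromixError(Exception):
    """Base class for all aromix errors."""


class ValidationError(AromixError, ValueError):
    """An argument violates a documented precondition."""


class InvalidCurveError(AromixError):
    """A calibration curve cannot be used (e.g. zero slope)."""


class ConfigurationError(AromixError):
    """Required configuration (e.g. internal-standard concentration) is missing."""


class InsufficientDataError(AromixError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(AromixError):
    """The design matrix carries no information (e.g. zero variance in x)."""


class NonIdentifiableError(AromixError):
    """The model parameters are not identifiable from the data."""


class DesignViolationError(AromixError):
    """Data violate an assumption of the experimental design."""


class SchemaError(AromixError):
    """An input table is missing required columns or is otherwise malformed."""
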