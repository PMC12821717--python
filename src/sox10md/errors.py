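"""Exception hierarchy.

Distinct exception classes exist so the CLI can map failure modes to
distinct exit codes (configuration vs I/O vs degenerate input).
"""


class Sox10mdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(Sox10mdError):
    """Invalid or inconsistent configuration / scene specification."""


class GenerationError(Sox10mdError):
    """Synthetic scene cannot be realised (e.g. nest longer than the basal border)."""


class OrientationError(Sox10mdError):
    """Basal side of the epidermis cannot be determined."""


class FilterError(Sox10mdError):
    """Junctional filtering is impossible (no basal contours)."""


class UndefinedRateError(Sox10mdError):
    """A confusion-matrix rate has a zero denominator (single-class data)."""


class InsufficientPointsError(Sox10mdError):
    """Too few ROC points to integrate an area under the curve."""


class DomainError(Sox10mdError):
    """Numeric argument outside its mathematical domain."""


class InputError(Sox10mdError):
    """Malformed user-supplied tabular input (length mismatch, missing column)."""


class DegenerateInputError(Sox10mdError):
    """Input is readable but carries no analysable tissue."""
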