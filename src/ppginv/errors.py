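"""Exception hierarchy for ppginv.

All package-specific failures derive from :class:`PPGInvError` so callers can
catch one base class; the leaves also subclass the matching builtin
(``ValueError``/``KeyError``) for idiomatic handling.
"""


class PPGInvError(Exception):
    """Base class for all ppginv errors."""


class InvalidInputError(PPGInvError, ValueError):
    """Input data violates a documented precondition (non-finite samples,
    out-of-range parameter, malformed value)."""


class TooShortError(InvalidInputError):
    """Series is too short for the requested operation (filter padding,
    smoothing frame, or analysis windows)."""


class UndefinedEstimateError(PPGInvError):
    """A statistic is undefined for the given input (no symmetry-passing
    pulses, empty configuration cell); the recording/cell must be reported
    as excluded/missing rather than imputed."""


class DuplicateMeasurementError(PPGInvError, ValueError):
    """Two estimates share the same (participant, position, pressure, LED)
    key during grid aggregation."""


class SchemaError(PPGInvError, ValueError):
    """A file does not match the documented on-disk schema; the message
    names the offending column or field."""


class ConfigError(PPGInvError, ValueError):
    """Run configuration contains unknown keys or out-of-range values."""
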