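"""Exception hierarchy for the model.

All model-facing errors derive from :class:`ModelError` so callers can
catch one base class; the CLI maps them to exit code 2.
"""


class ModelError(Exception):
    """Base class for all package errors."""


class DomainError(ModelError, ValueError):
    """An argument lies outside its mathematical domain."""


class TableCoverageError(ModelError, KeyError):
    """An age-indexed table does not cover a requested age range."""


class ValidationError(ModelError, ValueError):
    """A parameter bundle or domain object violates an invariant."""


class CalibrationError(ModelError, ArithmeticError):
    """A calibration target cannot be reached without clamping."""


class ConsistencyError(ModelError, RuntimeError):
    """Probability mass was lost or created during cohort propagation."""


class ConfigError(ModelError, ValueError):
    """A configuration file or parameter path is malformed."""
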