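"""Exception hierarchy.

Every error raised deliberately by the package derives from :class:`QspsimError`
so callers can distinguish domain failures from programming bugs.
"""


class QspsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QspsimError):
    """A model, plugin or effect table is wired up inconsistently."""


class DomainError(QspsimError, ValueError):
    """An argument is outside its physical or mathematical domain."""


class ValidationError(QspsimError, ValueError):
    """A user-supplied definition (VP, protocol, schema) failed validation."""


class ConvergenceError(QspsimError, RuntimeError):
    """An iterative routine (steady state, calibration) did not converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CalibrationError(ConvergenceError):
    """Virtual-patient calibration failed to reach its targets."""


class UnitConversionError(QspsimError, KeyError):
    """No registered conversion between the requested units."""


class SerializationError(QspsimError, ValueError):
    """A task or result document is incomplete or malformed."""


class IntegrityError(QspsimError):
    """Stored results do not match their manifest."""
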