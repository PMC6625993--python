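"""Exception hierarchy for gradpump.

All package errors derive from :class:`GradpumpError` so callers can catch
one base class; most are also ``ValueError`` subclasses because they signal
bad inputs rather than internal faults.
"""


class GradpumpError(Exception):
    """Base class for all gradpump errors."""


class InvalidInput(GradpumpError, ValueError):
    """A profile or configuration argument is out of its physical domain."""


class InfeasibleDiscretization(GradpumpError, ValueError):
    """The requested interval count cannot accommodate the mandatory times."""


class InfeasibleTarget(GradpumpError, ValueError):
    """No finite dispense volume can reach the requested concentration.

    Raised when an increasing target meets or exceeds the stock concentration,
    or a decreasing target is exactly zero (finite dilution cannot reach 0).
    """


class DirectionViolation(GradpumpError, ValueError):
    """The target moves against the direction the solver was asked to serve."""


class FlaskDepleted(GradpumpError, RuntimeError):
    """The flask volume would drop to zero or below during the schedule."""


class InvalidMeasurement(GradpumpError, ValueError):
    """A cumulative dispense log is not physically consistent (decreasing)."""


class UndefinedNormalization(GradpumpError, ValueError):
    """Percent error cannot be formed (normalizing concentration is zero)."""


class ConfigError(GradpumpError, ValueError):
    """A run-spec file failed to parse or validate."""
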