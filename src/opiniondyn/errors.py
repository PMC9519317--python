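"""Exception hierarchy for opiniondyn."""


class OpinionDynError(Exception):
    """Base class for all opiniondyn errors."""


class ParameterValidationError(OpinionDynError, ValueError):
    """A parameter value violates its declared range or a model hypothesis."""


class DegenerateParameterError(OpinionDynError, ValueError):
    """A parameter combination makes the requested quantity undefined
    (zero denominator, singular transfer matrix, singular linear system)."""


class IntegrationError(OpinionDynError, RuntimeError):
    """The ODE solver failed to advance the solution.

    Attributes
    ----------
    t_fail : float or None
        Last time the solver reached before failing.
    """

    def __init__(self, message, t_fail=None):
        super().__init__(message)
        self.t_fail = t_fail


class RootFindingError(OpinionDynError, RuntimeError):
    """Equilibrium root finding did not converge.

    Carries the last iterate so callers can inspect how close it got.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class CalibrationError(OpinionDynError, RuntimeError):
    """Parameter calibration failed to converge; carries the best iterate."""

    def __init__(self, message, best_iterate=None):
        super().__init__(message)
        self.best_iterate = best_iterate


class ConsistencyError(OpinionDynError, RuntimeError):
    """Two independent computations of the same quantity disagree beyond
    tolerance (e.g. eigenvalue vs Routh-Hurwitz stability verdicts)."""


class ConfigError(OpinionDynError, ValueError):
    """A configuration file failed to parse or validate."""


class NegativityWarning(UserWarning):
    """A trajectory dipped below the negativity tolerance."""
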