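"""Exception hierarchy for ewsbench."""


class EwsBenchError(Exception):
    """Base class for all package errors."""


class DimensionError(EwsBenchError, ValueError):
    """Inconsistent array shapes between states, parameters or series."""


class PreconditionError(EwsBenchError, ValueError):
    """An input violates a documented precondition (e.g. negative abundances)."""


class ConvergenceError(EwsBenchError, RuntimeError):
    """An iterative solver exhausted its budget.

    Carries the best residual reached so callers can judge how close it got.
    """

    def __init__(self, message, residual=None, best_state=None):
        super().__init__(message)
        self.residual = residual
        self.best_state = best_state


class SweepError(EwsBenchError, RuntimeError):
    """An equilibrium branch was lost mid-sweep; ``step`` identifies where."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class SearchError(EwsBenchError, RuntimeError):
    """Random parameter search exhausted its budget.

    ``failure_counts`` maps acceptance-criterion names to how often each one
    rejected a candidate draw.
    """

    def __init__(self, message, failure_counts=None):
        super().__init__(message)
        self.failure_counts = dict(failure_counts or {})


class IntegrationError(EwsBenchError, RuntimeError):
    """The stochastic integrator produced a non-finite state."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class UndefinedStatisticError(EwsBenchError, ValueError):
    """A statistic is undefined for the given input (e.g. a constant series)."""


class DegenerateDataError(EwsBenchError, ValueError):
    """Data are rank deficient where full rank is required."""

    def __init__(self, message, null_directions=None):
        super().__init__(message)
        self.null_directions = null_directions


class NotApplicableError(EwsBenchError, ValueError):
    """An indicator is not defined for this input (e.g. multivariate-only on N=1)."""


class CatalogueError(EwsBenchError, KeyError):
    """Unknown indicator name; the message lists the valid catalogue."""


class EvaluationError(EwsBenchError, RuntimeError):
    """Too few valid sweep steps to score an indicator."""


class ConfigError(EwsBenchError, ValueError):
    """Invalid scenario or run configuration."""
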