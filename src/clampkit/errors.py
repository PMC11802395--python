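"""Exception hierarchy shared across clampkit modules."""


class ClampkitError(Exception):
    """Base class for all clampkit errors."""


class DomainError(ClampkitError, ValueError):
    """An input lies outside the mathematical/physiological domain of an operation."""


class ValidationError(ClampkitError, ValueError):
    """A table, config or parameter set violates its schema or invariants."""


class InsufficientDataError(ClampkitError, ValueError):
    """Too few samples (or too much missing data) to perform the requested analysis."""


class SteadyStateNotReachedError(ClampkitError, RuntimeError):
    """No window in the requested clamp phase satisfies the steady-state criterion."""


class AlignmentError(ClampkitError, ValueError):
    """Two curves expected on a common time grid are not aligned."""


class SimulationError(ClampkitError, RuntimeError):
    """A forward simulation failed (unstable controller, unreachable target...)."""


class SolverError(ClampkitError, RuntimeError):
    """A numerical solver failed to converge; carries diagnostic info."""
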