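"""Exception hierarchy for phoscycle.

All package-specific failures derive from :class:`PhosCycleError` so callers
can catch one base class at CLI or scripting boundaries.
"""


class PhosCycleError(Exception):
    """Base class for all phoscycle errors."""


class InvalidParameterError(PhosCycleError, ValueError):
    """A rate constant or total concentration violates its preconditions."""


class InvalidStateError(PhosCycleError, ValueError):
    """A species concentration is negative or otherwise inadmissible."""


class ConvergenceError(PhosCycleError, RuntimeError):
    """Time integration hit ``t_max`` before reaching steady state.

    Carries the last state reached as ``last_state``.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class DegenerateCubicError(PhosCycleError, ArithmeticError):
    """The steady-state cubic is (numerically) degenerate; use the numeric
    solver instead."""


class BracketError(PhosCycleError, ArithmeticError):
    """No sign change over the admissible root interval."""


class InternalConsistencyError(PhosCycleError, RuntimeError):
    """A closed-form result landed outside its analytically guaranteed range."""


class IndeterminateSwitchError(PhosCycleError, ArithmeticError):
    """Goldbeter-Koshland limit is singular (v1 == v2 with both Michaelis
    constants zero)."""


class InvalidProbabilityError(PhosCycleError, ValueError):
    """A probability argument lies outside [0, 1]."""


class NonIdentifiableError(PhosCycleError, ValueError):
    """A Michaelis constant cannot be recovered (zero complex measured)."""


class InconsistentMeasurementError(PhosCycleError, ValueError):
    """Measured concentrations contradict the stated totals."""


class MonotonicityError(PhosCycleError, ValueError):
    """A dose-response vector required to be monotone is not."""


class CoverageError(PhosCycleError, ValueError):
    """A dose-response grid does not span the 10%-90% response range."""


class InvalidRegimeError(PhosCycleError, ValueError):
    """A sampling regime specification has empty or inconsistent ranges."""


class InvalidConfigError(PhosCycleError, ValueError):
    """A scenario or CLI configuration is malformed."""
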