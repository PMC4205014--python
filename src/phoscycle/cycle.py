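"""Mass-action kinetics of a single phosphorylation-dephosphorylation cycle.

The reaction scheme is the classical push-pull loop

    W + K <-> WK -> Wp + K        (kinase branch:    a1, d1, k1)
    Wp + P <-> WpP -> W + P       (phosphatase branch: a2, d2, k2)

with three conserved totals: substrate (``W + Wp + WK + WpP``), kinase
(``K + WK``) and phosphatase (``P + WpP``).  Units are arbitrary but
consistent: concentrations in one nominal unit ("conc"), rates in 1/time
(first order) or 1/(conc*time) (association).

This module provides the ordinary-differential-equation description and a
stiff time integrator used as the brute-force oracle for the closed-form
steady-state solver in :mod:`phoscycle.closed_form`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, InvalidParameterError, InvalidStateError

__all__ = [
    "CycleParameters",
    "CycleState",
    "StateDerivative",
    "make_cycle_parameters",
    "default_initial_state",
    "reaction_rhs",
    "conservation_residuals",
    "integrate_to_steady_state",
    "simulate_time_course",
]


@dataclass(frozen=True)
class CycleParameters:
    """Rate constants and totals of one cycle, with derived Michaelis constants.

    Construct via :func:`make_cycle_parameters`, which validates inputs and
    fills in ``Km1 = (d1 + k1) / a1`` and ``Km2 = (d2 + k2) / a2``.
    """

    a1: float
    d1: float
    k1: float
    a2: float
    d2: float
    k2: float
    W_T: float
    K_T: float
    P_T: float
    Km1: float
    Km2: float

    def with_totals(self, *, W_T: float | None = None, K_T: float | None = None,
                    P_T: float | None = None) -> "CycleParameters":
        """Return a copy with one or more totals replaced (rates unchanged)."""
        return make_cycle_parameters(
            self.a1, self.d1, self.k1, self.a2, self.d2, self.k2,
            self.W_T if W_T is None else W_T,
            self.K_T if K_T is None else K_T,
            self.P_T if P_T is None else P_T,
        )

    def with_rates(self, **rates: float) -> "CycleParameters":
        """Return a copy with rate constants replaced; Km1/Km2 recomputed."""
        cur = dict(a1=self.a1, d1=self.d1, k1=self.k1,
                   a2=self.a2, d2=self.d2, k2=self.k2)
        unknown = set(rates) - set(cur)
        if unknown:
            raise InvalidParameterError(f"unknown rate constants: {sorted(unknown)}")
        cur.update(rates)
        return make_cycle_parameters(
            cur["a1"], cur["d1"], cur["k1"], cur["a2"], cur["d2"], cur["k2"],
            self.W_T, self.K_T, self.P_T)


@dataclass(frozen=True)
class CycleState:
    """Concentrations of the six species of the cycle."""

    W: float
    Wp: float
    WK: float
    WpP: float
    K: float
    P: float

    def as_array(self) -> np.ndarray:
        return np.array([self.W, self.Wp, self.WK, self.WpP, self.K, self.P])


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of each :class:`CycleState` field (conc/time)."""

    dW: float
    dWp: float
    dWK: float
    dWpP: float
    dK: float
    dP: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dW, self.dWp, self.dWK, self.dWpP, self.dK, self.dP])


def make_cycle_parameters(a1: float, d1: float, k1: float,
                          a2: float, d2: float, k2: float,
                          W_T: float, K_T: float, P_T: float) -> CycleParameters:
    """Validate inputs and build a :class:`CycleParameters`.

    Raises
    ------
    InvalidParameterError
        If any value is negative or non-finite, ``W_T <= 0``, or an
        association rate is zero while the paired enzyme total is positive
        (the corresponding Michaelis constant would be undefined).
    """
    values = dict(a1=a1, d1=d1, k1=k1, a2=a2, d2=d2, k2=k2,
                  W_T=W_T, K_T=K_T, P_T=P_T)
    for name, v in values.items():
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if v < 0:
            raise InvalidParameterError(f"{name} must be nonnegative, got {v!r}")
    if W_T <= 0:
        raise InvalidParameterError(f"W_T must be positive, got {W_T!r}")
    if K_T > 0 and a1 == 0:
        raise InvalidParameterError("a1 must be positive when K_T > 0")
    if P_T > 0 and a2 == 0:
        raise InvalidParameterError("a2 must be positive when P_T > 0")
    Km1 = (d1 + k1) / a1 if a1 > 0 else math.inf
    Km2 = (d2 + k2) / a2 if a2 > 0 else math.inf
    return CycleParameters(a1, d1, k1, a2, d2, k2, W_T, K_T, P_T, Km1, Km2)


def default_initial_state(params: CycleParameters) -> CycleState:
    """Resting state: all substrate unphosphorylated and free, all enzyme free."""
    return CycleState(W=params.W_T, Wp=0.0, WK=0.0, WpP=0.0,
                      K=params.K_T, P=params.P_T)


def reaction_rhs(state: CycleState, params: CycleParameters) -> StateDerivative:
    """Mass-action right-hand side of the cycle ODEs.

    The three conservation sums (substrate, kinase, phosphatase) are zero by
    construction: each flux enters the derivative vector with cancelling
    signs.
    """
    for name in ("W", "Wp", "WK", "WpP", "K", "P"):
        if getattr(state, name) < 0:
            raise InvalidStateError(
                f"negative concentration {name}={getattr(state, name)!r}")
    p = params
    bind1 = p.a1 * state.W * state.K          # W + K -> WK
    unbind1 = p.d1 * state.WK                 # WK -> W + K
    cat1 = p.k1 * state.WK                    # WK -> Wp + K
    bind2 = p.a2 * state.Wp * state.P         # Wp + P -> WpP
    unbind2 = p.d2 * state.WpP                # WpP -> Wp + P
    cat2 = p.k2 * state.WpP                   # WpP -> W + P
    return StateDerivative(
        dW=-bind1 + unbind1 + cat2,
        dWp=cat1 - bind2 + unbind2,
        dWK=bind1 - unbind1 - cat1,
        dWpP=bind2 - unbind2 - cat2,
        dK=-bind1 + unbind1 + cat1,
        dP=-bind2 + unbind2 + cat2,
    )


def conservation_residuals(state: CycleState,
                           params: CycleParameters) -> tuple[float, float, float]:
    """Deviations of the three conserved sums from their stated totals."""
    return (
        state.W + state.Wp + state.WK + state.WpP - params.W_T,
        state.K + state.WK - params.K_T,
        state.P + state.WpP - params.P_T,
    )


def _rate_scale(p: CycleParameters) -> float:
    scale = max(p.d1, p.d2, p.k1, p.k2,
                p.a1 * p.W_T if math.isfinite(p.a1) else 0.0,
                p.a2 * p.W_T if math.isfinite(p.a2) else 0.0)
    return scale if scale > 0 else 1.0


def _reduced_rhs(t, y, p: CycleParameters):
    # reduced coordinates (Wp, WK, WpP); W, K, P reconstructed from totals so
    # conservation is exact to rounding regardless of integrator error
    Wp, WK, WpP = y
    W = p.W_T - Wp - WK - WpP
    K = p.K_T - WK
    P = p.P_T - WpP
    bind1 = p.a1 * W * K
    bind2 = p.a2 * Wp * P
    return (p.k1 * WK - bind2 + p.d2 * WpP,
            bind1 - (p.d1 + p.k1) * WK,
            bind2 - (p.d2 + p.k2) * WpP)


def _reduced_jac(t, y, p: CycleParameters):
    Wp, WK, WpP = y
    W = p.W_T - Wp - WK - WpP
    K = p.K_T - WK
    P = p.P_T - WpP
    return [
        [-p.a2 * P, p.k1, p.a2 * Wp + p.d2],
        [-p.a1 * K, -p.a1 * (K + W) - (p.d1 + p.k1), -p.a1 * K],
        [p.a2 * P, 0.0, -p.a2 * Wp - (p.d2 + p.k2)],
    ]


def _full_state(y, p: CycleParameters) -> CycleState:
    Wp, WK, WpP = (max(float(v), 0.0) for v in y)
    return CycleState(W=max(p.W_T - Wp - WK - WpP, 0.0), Wp=Wp, WK=WK,
                      WpP=WpP, K=max(p.K_T - WK, 0.0), P=max(p.P_T - WpP, 0.0))


def simulate_time_course(params: CycleParameters, times: np.ndarray,
                         initial: CycleState | None = None) -> np.ndarray:
    """Integrate the cycle and sample all six species at ``times``.

    Returns an array of shape ``(len(times), 6)`` with columns ordered
    ``W, Wp, WK, WpP, K, P``.  ``times`` must start at 0 and increase.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or times[0] != 0.0 \
            or np.any(np.diff(times) <= 0):
        raise InvalidParameterError(
            "times must be 1-D, start at 0 and be strictly increasing")
    if initial is None:
        initial = default_initial_state(params)
    y0 = np.array([initial.Wp, initial.WK, initial.WpP], dtype=float)
    scale = max(params.W_T, params.K_T, params.P_T)
    sol = solve_ivp(_reduced_rhs, (0.0, float(times[-1])), y0, args=(params,),
                    method="BDF", jac=_reduced_jac, t_eval=times,
                    rtol=1e-10, atol=1e-13 * scale)
    if not sol.success:  # pragma: no cover
        raise ConvergenceError(f"integrator failed: {sol.message}")
    out = np.empty((times.size, 6))
    for i in range(times.size):
        st = _full_state(sol.y[:, i], params)
        out[i] = st.as_array()
    return out


def _near_fixed_point(y, dy, params: CycleParameters, rel_tol: float) -> bool:
    # A small derivative alone does not bound the distance to the fixed
    # point when the slowest eigenvalue is tiny; the Newton step |J^-1 f|
    # does (to first order).  Fall back to the derivative test if the
    # Jacobian is singular (e.g. no enzymes at all).
    J = np.asarray(_reduced_jac(0.0, y, params))
    try:
        step = np.linalg.solve(J, dy)
    except np.linalg.LinAlgError:
        return True
    return bool(np.max(np.abs(step)) < rel_tol * params.W_T)


def integrate_to_steady_state(params: CycleParameters,
                              initial: CycleState | None = None,
                              rel_tol: float = 1e-9,
                              t_max: float = 1e6) -> CycleState:
    """Integrate the cycle ODEs until steady state.

    Convergence requires both the derivative max-norm and the Newton step
    ``|J^-1 f|`` (a first-order bound on the distance to the fixed point)
    to drop below ``rel_tol * W_T``.

    The integration runs in reduced coordinates (``Wp``, ``WK``, ``WpP``)
    with the remaining species reconstructed from the conservation totals,
    so the conserved sums hold to rounding error throughout.  ``t_max`` is
    measured in model time units; exceeding it raises
    :class:`ConvergenceError` carrying the last state reached.
    """
    if initial is None:
        initial = default_initial_state(params)
    else:
        res = conservation_residuals(initial, params)
        tol = 1e-8 * max(params.W_T, params.K_T, params.P_T)
        if any(abs(r) > tol for r in res):
            raise InvalidStateError(
                f"initial state violates conservation totals: residuals {res}")
    y = np.array([initial.Wp, initial.WK, initial.WpP], dtype=float)
    scale = max(params.W_T, params.K_T, params.P_T)
    atol = 1e-12 * scale
    span = 50.0 / _rate_scale(params)
    elapsed = 0.0
    while True:
        dy = np.asarray(_reduced_rhs(0.0, y, params))
        if np.max(np.abs(dy)) < rel_tol * params.W_T and _near_fixed_point(
                y, dy, params, rel_tol):
            return _full_state(y, params)
        if elapsed >= t_max:
            raise ConvergenceError(
                f"no steady state within t_max={t_max}",
                last_state=_full_state(y, params))
        span = min(span, t_max - elapsed)
        sol = solve_ivp(_reduced_rhs, (0.0, span), y, args=(params,),
                        method="BDF", jac=_reduced_jac,
                        rtol=1e-8, atol=atol)
        if not sol.success:  # pragma: no cover - LSODA failure is exceptional
            raise ConvergenceError(f"integrator failed: {sol.message}",
                                   last_state=_full_state(y, params))
        y = sol.y[:, -1]
        elapsed += span
        span *= 10.0
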