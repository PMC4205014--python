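"""Closed-form steady state of the phosphorylation cycle with enzyme
sequestration.

Unlike the classical complex-free approximation (:mod:`phoscycle.gk`), the
solution here retains the Michaelis complexes ``WK`` and ``WpP``.  At steady
state the two catalytic fluxes balance, ``k1*WK = k2*WpP``, and with the
quasi-steady-state complex expressions

    WK  = K_T * W  / (Km1 + W),      WpP = P_T * Wp / (Km2 + Wp)

the whole system collapses to one scalar unknown.  We root the problem in
the *saturation variable*

    q = WpP / P_T = v * W/(Km1 + W) / 1 = Wp / (Km2 + Wp) * 1,

i.e. the phosphatase occupancy, which equals the kinase occupancy scaled by
the maximal-rate ratio ``v = k1*K_T / (k2*P_T)``.  Substituting into the
substrate conservation law gives the monotonically increasing function

    g(q) = kappa1*q/(v - q) + kappa2*q/(1 - q) + (eps_K/v + eps_P)*q - 1

whose unique zero on ``(0, q_max)`` is the steady state; clearing
denominators turns ``g`` into a cubic polynomial whose real root on the
admissible interval is computed in closed form (Cardano / trigonometric
branch via Vieta's substitution).

Convention: the single-site phosphorylation probability is

    p = (Wp + WpP) / W_T

-- every phosphorylated molecule counts, whether free or phosphatase-bound;
kinase-bound substrate is unphosphorylated.  This is the ``p`` consumed by
:mod:`phoscycle.multisite`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .cycle import CycleParameters, CycleState
from .errors import (
    BracketError,
    DegenerateCubicError,
    InternalConsistencyError,
    InvalidStateError,
)

__all__ = [
    "NondimensionalParameters",
    "CubicCoefficients",
    "SteadyStateSolution",
    "complex_concentrations",
    "nondimensionalize",
    "cubic_coefficients",
    "steady_state_function",
    "real_root",
    "solve_steady_state",
    "solve_steady_state_numeric",
]

logger = logging.getLogger(__name__)

_ROOT_SLACK = 1e-12


@dataclass(frozen=True)
class NondimensionalParameters:
    """Dimensionless groups of the cycle, all normalized by ``W_T``.

    ``v_ratio`` is the maximal-rate ratio ``k1*K_T / (k2*P_T)``; when the
    phosphatase flux capacity ``k2*P_T`` is zero it is reported as ``inf``
    with ``v_infinite`` set rather than raising.
    """

    kappa1: float
    kappa2: float
    eps_K: float
    eps_P: float
    v_ratio: float
    v_infinite: bool = False


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients ``c3*q**3 + c2*q**2 + c1*q + c0`` of the steady-state
    cubic in the saturation variable, plus the admissible root interval
    ``(0, domain_max)``."""

    c3: float
    c2: float
    c1: float
    c0: float
    domain_max: float

    def __call__(self, q: float) -> float:
        return ((self.c3 * q + self.c2) * q + self.c1) * q + self.c0

    def derivative(self, q: float) -> float:
        return (3.0 * self.c3 * q + 2.0 * self.c2) * q + self.c1


@dataclass(frozen=True)
class SteadyStateSolution:
    """Steady-state species, phosphorylation probability and root diagnostics.

    ``residual`` is the cubic evaluated at the root, scaled by the largest
    coefficient magnitude; ``method`` is ``"closed_form"`` or ``"numeric"``.
    """

    state: CycleState
    p: float
    root: float
    residual: float
    method: str


def complex_concentrations(freeW: float, freeWp: float,
                           params: CycleParameters) -> tuple[float, float]:
    """Quasi-steady-state complex concentrations given the free species."""
    if freeW < 0 or freeWp < 0:
        raise InvalidStateError(
            f"free concentrations must be nonnegative, got ({freeW}, {freeWp})")
    WK = params.K_T * freeW / (params.Km1 + freeW) if params.K_T > 0 else 0.0
    WpP = params.P_T * freeWp / (params.Km2 + freeWp) if params.P_T > 0 else 0.0
    return WK, WpP


def nondimensionalize(params: CycleParameters) -> NondimensionalParameters:
    """Normalize the cycle by the substrate total.

    Inverse mapping: ``Km1 = kappa1*W_T``, ``Km2 = kappa2*W_T``,
    ``K_T = eps_K*W_T``, ``P_T = eps_P*W_T`` and
    ``k1/k2 = v_ratio * eps_P/eps_K`` (absolute rate scales are not
    recoverable from the dimensionless groups alone).
    """
    v2 = params.k2 * params.P_T
    v1 = params.k1 * params.K_T
    if v2 > 0:
        return NondimensionalParameters(
            kappa1=params.Km1 / params.W_T, kappa2=params.Km2 / params.W_T,
            eps_K=params.K_T / params.W_T, eps_P=params.P_T / params.W_T,
            v_ratio=v1 / v2)
    return NondimensionalParameters(
        kappa1=params.Km1 / params.W_T, kappa2=params.Km2 / params.W_T,
        eps_K=params.K_T / params.W_T, eps_P=params.P_T / params.W_T,
        v_ratio=math.inf, v_infinite=True)


def _domain_max(nd: NondimensionalParameters) -> float:
    # q < v/(1+kappa1) keeps free substrate below W_T; q < 1/(1+kappa2)
    # keeps free phosphosubstrate below W_T.  Both follow from conservation.
    return min(nd.v_ratio / (1.0 + nd.kappa1), 1.0 / (1.0 + nd.kappa2))


def cubic_coefficients(nd: NondimensionalParameters) -> CubicCoefficients:
    """Build the steady-state cubic ``F(q) = (v - q)(1 - q) g(q)``.

    ``F`` has exactly one root on the admissible interval for positive
    parameters: ``g`` is strictly increasing there and the prefactor is
    strictly positive.  The leading coefficient ``eps_K/v + eps_P`` vanishes
    only when both enzyme totals are zero (handled upstream), in which case
    a :class:`DegenerateCubicError` is raised.
    """
    for name in ("kappa1", "kappa2", "eps_K", "eps_P", "v_ratio"):
        val = getattr(nd, name)
        if not math.isfinite(val) or val < 0:
            raise DegenerateCubicError(
                f"nondimensional parameter {name}={val!r} outside cubic domain")
    v = nd.v_ratio
    if v <= 0:
        raise DegenerateCubicError("v_ratio must be positive for the cubic")
    E = nd.eps_K / v + nd.eps_P
    if E == 0.0:
        raise DegenerateCubicError(
            "leading coefficient vanishes (both enzyme totals zero); "
            "use the numeric solver")
    k1k2 = nd.kappa1 + nd.kappa2
    return CubicCoefficients(
        c3=E,
        c2=-(E * (1.0 + v) + 1.0 + k1k2),
        c1=E * v + 1.0 + v + nd.kappa1 + nd.kappa2 * v,
        c0=-v,
        domain_max=_domain_max(nd),
    )


def steady_state_function(nd: NondimensionalParameters):
    """Return ``(g, g')`` for the monotone steady-state balance.

    ``g`` is strictly increasing on ``(0, min(1, v))`` -- its derivative
    ``kappa1*v/(v-q)**2 + kappa2/(1-q)**2 + eps_K/v + eps_P`` is positive
    for any admissible ``q`` -- so it crosses zero exactly once, which is
    the uniqueness argument for the steady state.
    """
    v = nd.v_ratio
    E = nd.eps_K / v + nd.eps_P

    def g(q: float) -> float:
        return (nd.kappa1 * q / (v - q) + nd.kappa2 * q / (1.0 - q)
                + E * q - 1.0)

    def dg(q: float) -> float:
        return (nd.kappa1 * v / (v - q) ** 2 + nd.kappa2 / (1.0 - q) ** 2 + E)

    return g, dg


def _cbrt(x: float) -> float:
    return math.copysign(abs(x) ** (1.0 / 3.0), x)


def real_root(coeffs: CubicCoefficients) -> float:
    """Closed-form real root of the steady-state cubic on its admissible
    interval.

    The cubic is depressed by Vieta's substitution ``q = t - c2/(3*c3)``;
    depending on the discriminant the single real root (Cardano) or the
    in-domain member of the trigonometric triple is taken, then polished by
    Newton steps.  If a unique in-domain root cannot be isolated the
    function raises :class:`DegenerateCubicError` (callers fall back to
    bisection); a root that fails to zero the polynomial raises
    :class:`InternalConsistencyError`.
    """
    a, b, c, d = coeffs.c3, coeffs.c2, coeffs.c1, coeffs.c0
    if a == 0.0 or not all(map(math.isfinite, (a, b, c, d))):
        raise DegenerateCubicError("leading coefficient zero or non-finite")
    shift = b / (3.0 * a)
    p = c / a - shift * b / a  # = (3ac - b^2) / (3a^2)
    qd = ((2.0 * shift * shift - c / a) * shift + d / a)
    disc = -4.0 * p ** 3 - 27.0 * qd ** 2
    dmax = coeffs.domain_max
    slack = _ROOT_SLACK * max(1.0, dmax)
    # the in-domain steady-state root is always simple (the monotone balance
    # has positive derivative there), so a near-zero discriminant signals a
    # collision of the *other* two roots; Newton polish recovers the target
    # root from either branch's candidates
    if disc < 0.0:
        # one real root: stable Cardano (avoid cancellation between cube roots)
        s = math.sqrt(max(qd * qd / 4.0 + p ** 3 / 27.0, 0.0))
        u = _cbrt(-qd / 2.0 - s) if qd > 0 else _cbrt(-qd / 2.0 + s)
        t = u + (0.0 if u == 0.0 else -p / (3.0 * u))
        candidates = [t - shift]
    elif p < 0.0:
        # three real roots: trigonometric form, keep those in the domain
        m = 2.0 * math.sqrt(-p / 3.0)
        theta = math.acos(max(-1.0, min(1.0, 3.0 * qd / (p * m)))) / 3.0
        candidates = [m * math.cos(theta - 2.0 * math.pi * k / 3.0) - shift
                      for k in range(3)]
    else:  # disc >= 0 with p >= 0 forces p = qd = 0: a triple root
        candidates = [-shift]
    in_domain = []
    for x in candidates:
        # Newton polish against the original coefficients
        for _ in range(3):
            fx = coeffs(x)
            dfx = coeffs.derivative(x)
            if dfx != 0.0 and math.isfinite(fx):
                x -= fx / dfx
        if -slack <= x <= dmax + slack:
            in_domain.append(x)
    if len(in_domain) > 1:  # polishing may collapse candidates onto one root
        spread = max(in_domain) - min(in_domain)
        if spread <= 1e-9 * max(1.0, dmax):
            in_domain = [in_domain[0]]
    if len(in_domain) != 1:
        raise DegenerateCubicError(
            f"could not isolate a unique root in [0, {dmax}]: "
            f"candidates {candidates}")
    x = in_domain[0]
    scale = max(abs(a), abs(b), abs(c), abs(d))
    if abs(coeffs(x)) > 1e-8 * scale:
        raise InternalConsistencyError(
            f"closed-form root {x} leaves residual {coeffs(x) / scale}")
    return min(max(x, 0.0), dmax)


def _reconstruct(params: CycleParameters, nd: NondimensionalParameters,
                 q: float, residual: float, method: str) -> SteadyStateSolution:
    v = nd.v_ratio
    W_T = params.W_T
    W = W_T * nd.kappa1 * q / (v - q)
    Wp = W_T * nd.kappa2 * q / (1.0 - q)
    WK = params.K_T * q / v
    WpP = params.P_T * q
    state = CycleState(W=W, Wp=Wp, WK=WK, WpP=WpP,
                       K=params.K_T - WK, P=params.P_T - WpP)
    p = (Wp + WpP) / W_T
    return SteadyStateSolution(state=state, p=min(max(p, 0.0), 1.0),
                               root=q, residual=residual, method=method)


def _saturating_pool(total_sub: float, total_enz: float, Km: float) -> float:
    """Free concentration x solving x + total_enz*x/(Km + x) = total_sub."""
    if total_enz == 0.0 or not math.isfinite(Km):
        return total_sub
    # x^2 + (Km + total_enz - total_sub) x - Km*total_sub = 0, positive root
    b = Km + total_enz - total_sub
    disc = math.sqrt(b * b + 4.0 * Km * total_sub)
    return 2.0 * Km * total_sub / (b + disc) if b >= 0 else (disc - b) / 2.0


def _one_sided(params: CycleParameters, phosphorylated: bool,
               method: str) -> SteadyStateSolution:
    """Steady state when one catalytic flux capacity is zero.

    With no phosphorylation flux all substrate collects in the ``W``/``WK``
    pool (p = 0); with no dephosphorylation flux it collects in
    ``Wp``/``WpP`` (p = 1).  The pool split is a plain binding equilibrium.
    """
    if phosphorylated:
        Wp = _saturating_pool(params.W_T, params.P_T, params.Km2)
        WpP = params.W_T - Wp
        state = CycleState(W=0.0, Wp=Wp, WK=0.0, WpP=WpP,
                           K=params.K_T, P=params.P_T - WpP)
        return SteadyStateSolution(state=state, p=1.0, root=math.nan,
                                   residual=0.0, method=method)
    W = _saturating_pool(params.W_T, params.K_T, params.Km1)
    WK = params.W_T - W
    state = CycleState(W=W, Wp=0.0, WK=WK, WpP=0.0,
                       K=params.K_T - WK, P=params.P_T)
    return SteadyStateSolution(state=state, p=0.0, root=math.nan,
                               residual=0.0, method=method)


def solve_steady_state(params: CycleParameters) -> SteadyStateSolution:
    """Closed-form steady state of the cycle.

    Degenerate cubics (discriminant at rounding level) fall back to
    :func:`solve_steady_state_numeric` with a logged notice.
    """
    if params.k1 * params.K_T == 0.0:
        return _one_sided(params, phosphorylated=False, method="closed_form")
    if params.k2 * params.P_T == 0.0:
        return _one_sided(params, phosphorylated=True, method="closed_form")
    nd = nondimensionalize(params)
    coeffs = cubic_coefficients(nd)
    try:
        q = real_root(coeffs)
    except DegenerateCubicError as exc:
        logger.info("closed-form root degenerate (%s); using numeric solver", exc)
        return solve_steady_state_numeric(params)
    scale = max(abs(coeffs.c3), abs(coeffs.c2), abs(coeffs.c1), abs(coeffs.c0))
    return _reconstruct(params, nd, q, coeffs(q) / scale, "closed_form")


def solve_steady_state_numeric(params: CycleParameters) -> SteadyStateSolution:
    """Steady state via bracketed Brent root-finding on the monotone balance
    function; independent oracle for :func:`solve_steady_state`."""
    if params.k1 * params.K_T == 0.0:
        return _one_sided(params, phosphorylated=False, method="numeric")
    if params.k2 * params.P_T == 0.0:
        return _one_sided(params, phosphorylated=True, method="numeric")
    nd = nondimensionalize(params)
    g, _ = steady_state_function(nd)
    hi = min(1.0, nd.v_ratio) * (1.0 - 1e-13)
    glo, ghi = g(0.0), g(hi)
    if not (glo < 0.0 < ghi):
        raise BracketError(
            f"no sign change on [0, {hi}]: g(0)={glo}, g(hi)={ghi}")
    q = brentq(g, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    coeffs = cubic_coefficients(nd)
    scale = max(abs(coeffs.c3), abs(coeffs.c2), abs(coeffs.c1), abs(coeffs.c0))
    return _reconstruct(params, nd, q, coeffs(q) / scale, "numeric")
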