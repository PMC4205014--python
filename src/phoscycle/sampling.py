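"""Seeded generation of parameter sets and synthetic measured states.

Parameter sets are drawn log-uniformly in the dimensionless groups that
govern the cycle's behaviour (enzyme:substrate ratios, normalized Michaelis
constants, catalytic rate ratio) and then lifted to concrete rate constants
and totals.  Three named regimes mirror the conditions the solvers are
contrasted under: deep substrate excess (where the complex-free
approximation is valid), comparable enzyme and substrate concentrations,
and phosphatase excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .closed_form import solve_steady_state
from .cycle import CycleParameters, make_cycle_parameters
from .errors import InvalidRegimeError
from .km import MeasuredState

__all__ = ["RegimeSpec", "REGIMES", "regime", "sample_parameters",
           "make_measured_state"]

_REGIME_EPS = {
    "substrate_excess": ((1e-4, 1e-3), (1e-4, 1e-3)),
    "comparable": ((0.3, 3.0), (0.3, 3.0)),
    "phosphatase_excess": ((0.3, 3.0), (3.0, 30.0)),
}

_DEFAULT_RANGES = {
    "kappa1": (1e-3, 1e3),
    "kappa2": (1e-3, 1e3),
    "rate_ratio": (1e-3, 1e3),   # k1/k2
    "W_T": (0.1, 10.0),
}


@dataclass(frozen=True)
class RegimeSpec:
    """Named sampling regime with log-uniform ranges and a seed."""

    name: str
    eps_K: tuple[float, float]
    eps_P: tuple[float, float]
    kappa1: tuple[float, float] = _DEFAULT_RANGES["kappa1"]
    kappa2: tuple[float, float] = _DEFAULT_RANGES["kappa2"]
    rate_ratio: tuple[float, float] = _DEFAULT_RANGES["rate_ratio"]
    W_T: tuple[float, float] = _DEFAULT_RANGES["W_T"]
    seed: int = 0

    def __post_init__(self):
        for fname in ("eps_K", "eps_P", "kappa1", "kappa2", "rate_ratio", "W_T"):
            lo, hi = getattr(self, fname)
            if not (0 < lo <= hi) or not np.isfinite(hi):
                raise InvalidRegimeError(
                    f"range {fname}=({lo}, {hi}) must be positive, finite, "
                    "and ordered")


def regime(name: str, seed: int = 0, **overrides) -> RegimeSpec:
    """Build one of the named regimes; range overrides are keyword args."""
    if name not in _REGIME_EPS:
        raise InvalidRegimeError(
            f"unknown regime {name!r}; choose from {sorted(_REGIME_EPS)}")
    eK, eP = _REGIME_EPS[name]
    kwargs = dict(name=name, eps_K=eK, eps_P=eP, seed=seed)
    kwargs.update(overrides)
    return RegimeSpec(**kwargs)


REGIMES = tuple(_REGIME_EPS)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameters(spec: RegimeSpec, count: int) -> list[CycleParameters]:
    """Draw ``count`` reproducible parameter sets within the regime's ranges.

    Rates and totals are strictly positive by construction; the split of
    each Michaelis constant into dissociation and catalytic parts is drawn
    from a moderate range so no group degenerates.
    """
    if count < 1:
        raise InvalidRegimeError(f"count must be positive, got {count!r}")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(count):
        W_T = _log_uniform(rng, *spec.W_T)
        kap1 = _log_uniform(rng, *spec.kappa1)
        kap2 = _log_uniform(rng, *spec.kappa2)
        eps_K = _log_uniform(rng, *spec.eps_K)
        eps_P = _log_uniform(rng, *spec.eps_P)
        ratio = _log_uniform(rng, *spec.rate_ratio)
        k2 = _log_uniform(rng, 0.3, 3.0)
        k1 = ratio * k2
        d1 = _log_uniform(rng, 0.3, 3.0)
        d2 = _log_uniform(rng, 0.3, 3.0)
        a1 = (d1 + k1) / (kap1 * W_T)
        a2 = (d2 + k2) / (kap2 * W_T)
        out.append(make_cycle_parameters(a1, d1, k1, a2, d2, k2,
                                         W_T, eps_K * W_T, eps_P * W_T))
    return out


def make_measured_state(params: CycleParameters, rel_noise: float,
                        seed: int) -> MeasuredState:
    """Solve the steady state and corrupt each species with independent
    multiplicative lognormal noise of relative sd ``rel_noise``.

    ``rel_noise = 0`` returns the exact steady-state species.  Totals are
    reported exactly (they are *known*, not measured).
    """
    if rel_noise < 0:
        raise InvalidRegimeError(f"rel_noise must be >= 0, got {rel_noise!r}")
    state = solve_steady_state(params).state
    rng = np.random.default_rng(seed)
    noise = (np.exp(rng.normal(0.0, rel_noise, size=4)) if rel_noise > 0
             else np.ones(4))
    return MeasuredState(
        W=state.W * noise[0], Wp=state.Wp * noise[1],
        WK=min(state.WK * noise[2], params.K_T),
        WpP=min(state.WpP * noise[3], params.P_T),
        K_T=params.K_T, P_T=params.P_T, W_T=params.W_T,
        rel_noise=rel_noise or None)
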