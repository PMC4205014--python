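"""Classical Goldbeter-Koshland approximation and its validity diagnostic.

The complex-free steady-state balance

    v1 * (1 - phi) / (kappa1 + 1 - phi) = v2 * phi / (kappa2 + phi)

treats the Michaelis complexes as negligible, which is justified only when
both enzyme totals are small against the substrate total.  ``gk_fraction``
evaluates the stable quadratic branch; ``gk_validity_check`` flags whether
the premise holds for a given parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .closed_form import nondimensionalize
from .cycle import CycleParameters
from .errors import IndeterminateSwitchError, InvalidParameterError

__all__ = ["GKInputs", "GKValidityReport", "gk_inputs", "gk_fraction",
           "gk_validity_check"]


@dataclass(frozen=True)
class GKInputs:
    """Maximal rates ``v1 = k1*K_T``, ``v2 = k2*P_T`` and Michaelis constants
    normalized by the substrate total."""

    v1: float
    v2: float
    kappa1: float
    kappa2: float


@dataclass(frozen=True)
class GKValidityReport:
    valid: bool
    eps_K: float
    eps_P: float
    threshold: float


def gk_inputs(params: CycleParameters) -> GKInputs:
    """Map full cycle parameters onto the complex-free approximation."""
    return GKInputs(v1=params.k1 * params.K_T, v2=params.k2 * params.P_T,
                    kappa1=params.Km1 / params.W_T,
                    kappa2=params.Km2 / params.W_T)


def gk_fraction(inputs: GKInputs) -> float:
    """Phosphorylated fraction of the complex-free balance, in [0, 1].

    Uses the subtraction-free quadratic branch

        phi = 2*v1*kappa2 / (B + sqrt(B**2 + 4*(v1 - v2)*v1*kappa2)),
        B   = v2 - v1 + v1*kappa2 + v2*kappa1,

    which avoids the cancellation the naive quadratic formula suffers in
    the zero-order (small kappa) regime.

    Raises
    ------
    IndeterminateSwitchError
        At the zero-order singular point ``v1 == v2`` with
        ``kappa1 == kappa2 == 0``, where every fraction balances.
    """
    v1, v2, kap1, kap2 = inputs.v1, inputs.v2, inputs.kappa1, inputs.kappa2
    if min(v1, v2, kap1, kap2) < 0:
        raise InvalidParameterError("GK inputs must be nonnegative")
    if v1 == 0.0:
        return 0.0
    if v2 == 0.0:
        return 1.0
    if kap1 == 0.0 and kap2 == 0.0:
        if v1 == v2:
            raise IndeterminateSwitchError(
                "v1 == v2 with both Michaelis constants zero")
        return 1.0 if v1 > v2 else 0.0
    B = v2 - v1 + v1 * kap2 + v2 * kap1
    if v1 == v2:
        return v1 * kap2 / B  # quadratic degenerates to a linear balance
    if kap2 == 0.0:
        # roots are 0 and 1 + v2*kap1/(v2 - v1); the positive branch only
        # exists when the kinase can outrun the (infinitely avid) phosphatase
        other = 1.0 + v2 * kap1 / (v2 - v1)
        return min(max(other, 0.0), 1.0) if v1 > v2 else 0.0
    disc = B * B + 4.0 * (v1 - v2) * v1 * kap2
    root = math.sqrt(max(disc, 0.0))
    if B + root > 0.0:
        phi = 2.0 * v1 * kap2 / (B + root)
    else:  # B < 0 and |B| ~ root: use the explicit branch
        phi = (-B + root) / (2.0 * (v1 - v2))
    return min(max(phi, 0.0), 1.0)


def gk_validity_check(params: CycleParameters,
                      threshold: float = 0.01) -> GKValidityReport:
    """Flag whether the complex-free premise holds: both enzyme:substrate
    ratios at or below ``threshold`` (default 1%)."""
    nd = nondimensionalize(params)
    return GKValidityReport(
        valid=max(nd.eps_K, nd.eps_P) <= threshold,
        eps_K=nd.eps_K, eps_P=nd.eps_P, threshold=threshold)
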