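"""Multisite phosphorylation with independent, identical sites.

An ``n``-site protein at total concentration ``W_T`` exposes ``n*W_T`` of
phosphorylatable sites, each cycling through the same kinase/phosphatase
loop.  The single-site solver run with the substrate total rescaled to
``n*W_T`` (enzyme totals unchanged) yields the per-site phosphorylation
probability ``p``; independence then makes the phosphoform class
abundances binomial:

    [m of n sites phosphorylated] = W_T * C(n, m) * p**m * (1-p)**(n-m).

``effective_hill`` quantifies switch steepness of a monotone dose-response
as ``log(81) / log(EC90 / EC10)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .closed_form import solve_steady_state
from .cycle import CycleParameters
from .errors import (
    CoverageError,
    InvalidParameterError,
    InvalidProbabilityError,
    MonotonicityError,
)

__all__ = ["MultisiteDistribution", "site_probability", "species_distribution",
           "effective_hill"]


@dataclass(frozen=True)
class MultisiteDistribution:
    """Concentrations of the ``n + 1`` phosphoform classes.

    ``species[m]`` is the concentration of protein with exactly ``m`` sites
    phosphorylated; the vector sums to ``total``.
    """

    n: int
    p: float
    total: float
    species: np.ndarray

    def fractions(self) -> np.ndarray:
        return self.species / self.total if self.total > 0 else self.species


def site_probability(params: CycleParameters, n: int) -> float:
    """Per-site phosphorylation probability of an ``n``-site protein.

    Solves the single-site closed form with the substrate total replaced by
    the site total ``n * W_T``; enzyme totals and rate constants are kept
    as given.  ``n = 1`` reduces to the plain single-site solution.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"n must be a positive integer, got {n!r}")
    site_params = params.with_totals(W_T=n * params.W_T)
    return solve_steady_state(site_params).p


def species_distribution(p: float, n: int, total: float) -> MultisiteDistribution:
    """Binomial phosphoform distribution for per-site probability ``p``."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"n must be a positive integer, got {n!r}")
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise InvalidProbabilityError(f"p must lie in [0, 1], got {p!r}")
    if total < 0:
        raise InvalidParameterError(f"total must be nonnegative, got {total!r}")
    # math.comb is exact; powers of p are the only rounding source
    species = np.array([
        total * math.comb(n, m) * p ** m * (1.0 - p) ** (n - m)
        for m in range(n + 1)
    ])
    return MultisiteDistribution(n=int(n), p=p, total=total, species=species)


def effective_hill(dose: np.ndarray, response: np.ndarray) -> float:
    """Model-free steepness of a monotone dose-response.

    ``n_H = log(81) / log(EC90 / EC10)`` with EC10/EC90 the doses at 10% and
    90% of the response's own maximum, obtained by monotone interpolation on
    a log-dose axis.

    Raises
    ------
    MonotonicityError
        If the response decreases anywhere (beyond rounding).
    CoverageError
        If the grid does not span the 10%-90% response range.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.ndim != 1 or dose.shape != response.shape or dose.size < 3:
        raise InvalidParameterError("dose and response must be 1-D, equal "
                                    "length, size >= 3")
    if np.any(dose <= 0) or np.any(np.diff(dose) <= 0):
        raise InvalidParameterError("dose must be positive, strictly increasing")
    rmax = float(np.max(response))
    if rmax <= 0:
        raise CoverageError("response is identically nonpositive")
    if np.any(np.diff(response) < -1e-9 * rmax):
        raise MonotonicityError("response is not monotone non-decreasing")
    lo, hi = 0.1 * rmax, 0.9 * rmax
    if response[0] > lo or rmax < hi:
        raise CoverageError(
            f"grid does not span 10%-90% of the response maximum "
            f"(first={response[0]:.3g}, max={rmax:.3g})")
    logd = np.log(dose)
    resp = np.maximum.accumulate(response)  # flatten rounding-level dips
    ec10 = float(np.interp(lo, resp, logd))
    ec90 = float(np.interp(hi, resp, logd))
    if ec90 <= ec10:
        raise CoverageError("EC90 does not exceed EC10 on this grid")
    return math.log(81.0) / (ec90 - ec10)
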