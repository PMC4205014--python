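"""Named sweep experiments for the two bundled signaling scenarios.

``stat3*`` scenarios model a single-site substrate (kinase JAK, phosphatase
SHP-1); ``irf5*`` scenarios model a six-site substrate (kinase TBK-1,
phosphatase alkaline phosphatase).  Each sweep moves either the
kinase:phosphatase total ratio (by rescaling the kinase total, phosphatase
held fixed) or the catalytic rate ratio ``k1/k2`` (by rescaling ``k1``)
over a log grid, solving the sequestration-aware closed form at every
point and optionally the complex-free approximation for comparison.

Bundled parameter sets are regime-representative (order-unity rates with
documented concentration ratios), not fits to any dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closed_form import nondimensionalize
from .cycle import CycleParameters, make_cycle_parameters
from .errors import CoverageError, InvalidConfigError, PhosCycleError
from .gk import gk_fraction, gk_inputs
from .multisite import effective_hill, site_probability, species_distribution

__all__ = ["ScenarioConfig", "SweepResult", "RegimeReport", "run_sweep",
           "regime_report", "bundled_scenario", "BUNDLED_SCENARIOS"]

SWEEP_AXES = ("kinase_total_ratio", "rate_ratio")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named dose-response sweep over one cycle parameterization."""

    name: str
    n_sites: int
    base_params: CycleParameters
    sweep_axis: str
    grid: np.ndarray
    compare_gk: bool = True

    def __post_init__(self):
        if self.sweep_axis not in SWEEP_AXES:
            raise InvalidConfigError(
                f"sweep_axis must be one of {SWEEP_AXES}, got {self.sweep_axis!r}")
        if not isinstance(self.n_sites, (int, np.integer)) or self.n_sites < 1:
            raise InvalidConfigError(f"n_sites must be >= 1, got {self.n_sites!r}")
        if self.name.startswith("stat3") and self.n_sites != 1:
            raise InvalidConfigError("stat3 scenarios are single-site")
        if self.name.startswith("irf5") and self.n_sites != 6:
            raise InvalidConfigError("irf5 scenarios have six sites")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise InvalidConfigError("grid must be a nonempty 1-D array")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise InvalidConfigError("grid must be positive, strictly increasing")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class SweepResult:
    """Tabulated dose-response of all phosphoform classes along the sweep."""

    name: str
    sweep_axis: str
    n_sites: int
    total: float
    axis: np.ndarray
    p: np.ndarray
    species: np.ndarray          # shape (len(axis), n_sites + 1)
    gk: np.ndarray | None
    meta: dict
    errors: tuple[tuple[int, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        data = {"axis": self.axis, "p": self.p}
        if self.gk is not None:
            data["gk"] = self.gk
        for m in range(self.n_sites + 1):
            data[f"species_{m}"] = self.species[:, m]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class RegimeReport:
    """Agreement/divergence of the closed form against the complex-free
    approximation, plus steepness metrics."""

    max_abs_diff: float
    agreement: bool
    divergence: bool
    hill_p: float
    hill_full: float
    eps_K: float
    eps_P: float

    AGREEMENT_TOL = 0.01


def _point_params(config: ScenarioConfig, value: float) -> CycleParameters:
    base = config.base_params
    if config.sweep_axis == "kinase_total_ratio":
        return base.with_totals(K_T=value * base.P_T)
    return base.with_rates(k1=value * base.k2)


def run_sweep(config: ScenarioConfig) -> SweepResult:
    """Solve the scenario at every grid point.

    Per-point solver failures are recorded in ``errors`` (row filled with
    NaN) rather than aborting the sweep.
    """
    n = config.n_sites
    npts = config.grid.size
    p = np.full(npts, np.nan)
    species = np.full((npts, n + 1), np.nan)
    gk = np.full(npts, np.nan) if config.compare_gk else None
    errors = []
    for i, value in enumerate(config.grid):
        try:
            pi = _point_params(config, float(value))
            p[i] = site_probability(pi, n)
            species[i] = species_distribution(p[i], n, pi.W_T).species
            if config.compare_gk:
                gk[i] = gk_fraction(gk_inputs(pi.with_totals(W_T=n * pi.W_T)))
        except PhosCycleError as exc:
            errors.append((i, str(exc)))
    site_base = config.base_params.with_totals(W_T=n * config.base_params.W_T)
    nd = nondimensionalize(site_base)
    meta = {"eps_K": nd.eps_K, "eps_P": nd.eps_P,
            "kappa1": nd.kappa1, "kappa2": nd.kappa2}
    return SweepResult(name=config.name, sweep_axis=config.sweep_axis,
                       n_sites=n, total=config.base_params.W_T,
                       axis=config.grid.copy(), p=p, species=species, gk=gk,
                       meta=meta, errors=tuple(errors))


def _safe_hill(axis: np.ndarray, response: np.ndarray) -> float:
    try:
        return effective_hill(axis, response)
    except CoverageError:
        return math.nan


def regime_report(result: SweepResult) -> RegimeReport:
    """Summarize a sweep run with ``compare_gk`` enabled."""
    if result.gk is None:
        raise InvalidConfigError("regime_report requires compare_gk sweeps")
    diff = np.abs(result.p - result.gk)
    max_diff = float(np.nanmax(diff))
    return RegimeReport(
        max_abs_diff=max_diff,
        agreement=max_diff < RegimeReport.AGREEMENT_TOL,
        divergence=max_diff >= RegimeReport.AGREEMENT_TOL,
        hill_p=_safe_hill(result.axis, result.p),
        hill_full=_safe_hill(result.axis, result.species[:, -1]),
        eps_K=result.meta["eps_K"], eps_P=result.meta["eps_P"])


def _base(K_T: float, P_T: float, Km1: float = 2.0,
          Km2: float = 2.0) -> CycleParameters:
    # order-unity rates; association rates chosen to hit the stated Km
    return make_cycle_parameters(a1=2.0 / Km1, d1=1.0, k1=1.0, a2=2.0 / Km2,
                                 d2=1.0, k2=1.0, W_T=1.0, K_T=K_T, P_T=P_T)


_GRID = np.logspace(-2, 2, 50)
# the weak-binding phosphatase shifts the irf5 transition left; start lower
# so the unphosphorylated class dominates at the low end of the sweep
_IRF5_GRID = np.logspace(-3, 2, 50)

# irf5 binding: tight kinase (Km1 = 0.05 of the 6-site total), weak
# phosphatase (Km2 = 20x) -- the regime where comparable enzyme totals
# suppress every phosphoform relative to substrate excess
_IRF5_KM1, _IRF5_KM2 = 0.3, 120.0


def _bundled() -> dict[str, ScenarioConfig]:
    # enzyme totals stated relative to the *site* total n*W_T
    return {
        # substrate excess: enzymes at 1e-4 of the site total
        "stat3": ScenarioConfig("stat3", 1, _base(1e-4, 1e-4),
                                "kinase_total_ratio", _GRID),
        # comparable: phosphatase on par with the substrate
        "stat3_comparable": ScenarioConfig("stat3_comparable", 1,
                                           _base(1.0, 1.0),
                                           "kinase_total_ratio", _GRID),
        # rate-ratio sweep at comparable totals (amplitude modulation regime)
        "stat3_rates": ScenarioConfig("stat3_rates", 1, _base(1.0, 1.0),
                                      "rate_ratio", _GRID),
        "irf5": ScenarioConfig("irf5", 6,
                               _base(6e-4, 6e-4, _IRF5_KM1, _IRF5_KM2),
                               "kinase_total_ratio", _IRF5_GRID),
        "irf5_comparable": ScenarioConfig("irf5_comparable", 6,
                                          _base(6.0, 6.0, _IRF5_KM1, _IRF5_KM2),
                                          "kinase_total_ratio", _IRF5_GRID),
        "irf5_rates": ScenarioConfig("irf5_rates", 6,
                                     _base(6.0, 6.0, _IRF5_KM1, _IRF5_KM2),
                                     "rate_ratio", _IRF5_GRID),
        "irf5_rates_excess": ScenarioConfig("irf5_rates_excess", 6,
                                            _base(6e-4, 6e-4, _IRF5_KM1,
                                                  _IRF5_KM2),
                                            "rate_ratio", _IRF5_GRID),
    }


BUNDLED_SCENARIOS = tuple(sorted(_bundled()))


def bundled_scenario(name: str) -> ScenarioConfig:
    """Look up a bundled scenario by name."""
    table = _bundled()
    if name not in table:
        raise InvalidConfigError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(table))}")
    return table[name]
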