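"""Recovery of Michaelis constants from measured steady-state concentrations.

Inverting the quasi-steady-state complex expressions gives direct,
fit-free estimators

    Km1 = W  * (K_T - WK)  / WK,       Km2 = Wp * (P_T - WpP) / WpP,

usable whenever the free species and complexes can be measured and the
totals are known.  Replicate estimates are summarized by the median, which
is robust to the heavy right tail these ratio estimators have under
multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable

from .errors import (
    InconsistentMeasurementError,
    InvalidStateError,
    NonIdentifiableError,
)

__all__ = ["MeasuredState", "estimate_km1", "estimate_km2",
           "estimate_michaelis_constants", "estimate_from_replicates"]


@dataclass(frozen=True)
class MeasuredState:
    """Measured steady-state species plus the known totals.

    ``rel_noise`` is an optional annotation of the relative measurement sd;
    it does not affect the point estimates.
    """

    W: float
    Wp: float
    WK: float
    WpP: float
    K_T: float
    P_T: float
    W_T: float
    rel_noise: float | None = None

    def __post_init__(self):
        for name in ("W", "Wp", "WK", "WpP", "K_T", "P_T", "W_T"):
            if getattr(self, name) < 0:
                raise InvalidStateError(
                    f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if self.WK > self.K_T:
            raise InconsistentMeasurementError(
                f"WK={self.WK} exceeds K_T={self.K_T}")
        if self.WpP > self.P_T:
            raise InconsistentMeasurementError(
                f"WpP={self.WpP} exceeds P_T={self.P_T}")


def estimate_km1(m: MeasuredState) -> float:
    """Kinase-step Michaelis constant from one measured state."""
    if m.WK == 0.0:
        raise NonIdentifiableError("WK = 0: Km1 is not identifiable")
    return m.W * (m.K_T - m.WK) / m.WK


def estimate_km2(m: MeasuredState) -> float:
    """Phosphatase-step Michaelis constant from one measured state."""
    if m.WpP == 0.0:
        raise NonIdentifiableError("WpP = 0: Km2 is not identifiable")
    return m.Wp * (m.P_T - m.WpP) / m.WpP


def estimate_michaelis_constants(m: MeasuredState) -> tuple[float, float]:
    """Both Michaelis constants from one measured state; raises
    :class:`NonIdentifiableError` if either complex measurement is zero."""
    return estimate_km1(m), estimate_km2(m)


def estimate_from_replicates(
        measurements: Iterable[MeasuredState]) -> tuple[float, float]:
    """Median per-replicate estimates of ``(Km1, Km2)``."""
    km1s, km2s = [], []
    for m in measurements:
        km1s.append(estimate_km1(m))
        km2s.append(estimate_km2(m))
    if not km1s:
        raise NonIdentifiableError("no measurements supplied")
    return median(km1s), median(km2s)
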