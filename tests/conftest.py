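import numpy as np
import pytest

from phoscycle import make_cycle_parameters, regime, sample_parameters


@pytest.fixture(scope="session")
def symmetric_params():
    """Fully exchange-symmetric cycle: a1=a2, d1=d2, k1=k2, K_T=P_T."""
    return make_cycle_parameters(a1=1.0, d1=1.0, k1=1.0, a2=1.0, d2=1.0,
                                 k2=1.0, W_T=1.0, K_T=0.5, P_T=0.5)


@pytest.fixture(scope="session")
def mixed_regime_params():
    """120 seeded parameter sets, 40 per regime."""
    sets = []
    for name in ("substrate_excess", "comparable", "phosphatase_excess"):
        sets.extend(sample_parameters(regime(name, seed=11), 40))
    return sets


@pytest.fixture(scope="session")
def small_regime_params():
    """A cheap 30-set sample for expensive (ODE-backed) tests."""
    sets = []
    for name in ("substrate_excess", "comparable", "phosphatase_excess"):
        sets.extend(sample_parameters(regime(name, seed=23), 10))
    return sets


def rel_diff(a, b, scale):
    return np.max(np.abs(np.asarray(a) - np.asarray(b))) / scale
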