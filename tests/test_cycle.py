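import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phoscycle import (
    CycleState,
    conservation_residuals,
    default_initial_state,
    integrate_to_steady_state,
    make_cycle_parameters,
    reaction_rhs,
    simulate_time_course,
    solve_steady_state,
)
from phoscycle.errors import (
    ConvergenceError,
    InvalidParameterError,
    InvalidStateError,
)


class TestMakeCycleParameters:
    def test_km_definition(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        assert p.Km1 == 2.0
        assert p.Km2 == 2.0

    def test_km_arithmetic(self):
        p = make_cycle_parameters(2, 0.5, 1.5, 4, 1, 1, 1, 1, 1)
        assert p.Km1 == 1.0
        assert p.Km2 == 0.5

    def test_zero_substrate_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_cycle_parameters(1, 1, 1, 1, 1, 1, 0.0, 1, 1)

    @pytest.mark.parametrize("field,value", [
        ("a1", -1.0), ("d2", -0.1), ("K_T", -2.0), ("k1", float("nan")),
    ])
    def test_bad_values_rejected(self, field, value):
        kwargs = dict(a1=1, d1=1, k1=1, a2=1, d2=1, k2=1, W_T=1, K_T=1, P_T=1)
        kwargs[field] = value
        with pytest.raises(InvalidParameterError):
            make_cycle_parameters(**kwargs)

    def test_zero_association_with_enzyme_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_cycle_parameters(0, 1, 1, 1, 1, 1, 1, 1, 1)
        # but fine when the paired enzyme total is zero
        p = make_cycle_parameters(0, 1, 1, 1, 1, 1, 1, 0, 1)
        assert p.K_T == 0.0

    def test_with_rates_recomputes_km(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        q = p.with_rates(k1=3.0)
        assert q.Km1 == 4.0
        assert q.Km2 == p.Km2


class TestReactionRhs:
    def test_zero_state_zero_derivative(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        d = reaction_rhs(CycleState(0, 0, 0, 0, 0, 0), p)
        assert np.all(d.as_array() == 0.0)

    def test_hand_evaluated_example(self):
        # binding flux only: W=K=1, everything else empty
        p = make_cycle_parameters(1, 0.5, 0.25, 2, 0.3, 0.7, 3, 1, 1)
        d = reaction_rhs(CycleState(W=1, Wp=0, WK=0, WpP=0, K=1, P=1), p)
        assert d.dWK == pytest.approx(1.0)   # a1*W*K
        assert d.dW == pytest.approx(-1.0)
        assert d.dK == pytest.approx(-1.0)
        assert d.dWp == 0.0
        assert d.dWpP == 0.0
        assert d.dP == 0.0

    def test_against_symbolic_mass_action(self):
        # independent symbolic evaluation of the reaction scheme
        sympy = pytest.importorskip("sympy")
        W, Wp, WK, WpP, K, P = sympy.symbols("W Wp WK WpP K P", positive=True)
        a1, d1, k1, a2, d2, k2 = sympy.symbols("a1 d1 k1 a2 d2 k2", positive=True)
        fluxes = {  # reaction: (rate expression, stoichiometry)
            "bind1": (a1 * W * K, {"W": -1, "K": -1, "WK": 1}),
            "unbind1": (d1 * WK, {"W": 1, "K": 1, "WK": -1}),
            "cat1": (k1 * WK, {"Wp": 1, "K": 1, "WK": -1}),
            "bind2": (a2 * Wp * P, {"Wp": -1, "P": -1, "WpP": 1}),
            "unbind2": (d2 * WpP, {"Wp": 1, "P": 1, "WpP": -1}),
            "cat2": (k2 * WpP, {"W": 1, "P": 1, "WpP": -1}),
        }
        species = ["W", "Wp", "WK", "WpP", "K", "P"]
        sym_rhs = {s: sum(rate * stoich.get(s, 0)
                          for rate, stoich in fluxes.values()) for s in species}
        subs = {a1: 1.3, d1: 0.7, k1: 2.1, a2: 0.9, d2: 1.8, k2: 0.4,
                W: 0.2, Wp: 0.5, WK: 0.1, WpP: 0.15, K: 0.3, P: 0.45}
        p = make_cycle_parameters(1.3, 0.7, 2.1, 0.9, 1.8, 0.4, 1.0, 0.4, 0.6)
        d = reaction_rhs(CycleState(0.2, 0.5, 0.1, 0.15, 0.3, 0.45), p)
        got = dict(zip(species, d.as_array()))
        for s in species:
            assert got[s] == pytest.approx(float(sym_rhs[s].subs(subs)), rel=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_structural_conservation(self, concs):
        p = make_cycle_parameters(1.1, 0.3, 0.8, 0.5, 0.2, 1.7, 1, 1, 1)
        d = reaction_rhs(CycleState(*concs), p)
        assert d.dW + d.dWp + d.dWK + d.dWpP == pytest.approx(0.0, abs=1e-12)
        assert d.dK + d.dWK == pytest.approx(0.0, abs=1e-12)
        assert d.dP + d.dWpP == pytest.approx(0.0, abs=1e-12)

    def test_negative_concentration_rejected(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(InvalidStateError):
            reaction_rhs(CycleState(-0.1, 0, 0, 0, 0, 0), p)


class TestConservationResiduals:
    def test_consistent_state_zero(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 2.0, 0.5, 0.25)
        assert conservation_residuals(default_initial_state(p), p) == (0, 0, 0)

    def test_inflation_shows_linearly(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 2.0, 0.5, 0.25)
        s = default_initial_state(p)
        inflated = CycleState(s.W + 0.125, s.Wp, s.WK, s.WpP, s.K, s.P)
        r = conservation_residuals(inflated, p)
        assert r[0] == pytest.approx(0.125)
        assert r[1] == 0.0 and r[2] == 0.0


class TestIntegrateToSteadyState:
    def test_no_kinase_no_phosphorylation(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1.0, 0.0, 0.5)
        s = integrate_to_steady_state(p)
        assert s.Wp == 0.0 and s.WpP == 0.0

    def test_no_phosphatase_full_phosphorylation(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1.0, 0.5, 0.0)
        s = integrate_to_steady_state(p)
        assert s.Wp == pytest.approx(1.0, rel=1e-6)
        assert s.W == pytest.approx(0.0, abs=1e-6)
        assert s.WK == pytest.approx(0.0, abs=1e-6)

    def test_conservation_of_terminal_state(self, mixed_regime_params):
        for p in mixed_regime_params[::6]:
            s = integrate_to_steady_state(p, t_max=1e12)
            r = conservation_residuals(s, p)
            assert abs(r[0]) < 1e-9 * p.W_T
            assert abs(r[1]) < 1e-9 * max(p.K_T, 1e-30)
            assert abs(r[2]) < 1e-9 * max(p.P_T, 1e-30)

    def test_inconsistent_initial_state_rejected(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(InvalidStateError):
            integrate_to_steady_state(p, initial=CycleState(2, 0, 0, 0, 1, 1))

    def test_nonconvergence_carries_last_state(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(ConvergenceError) as err:
            integrate_to_steady_state(p, rel_tol=1e-12, t_max=1e-4)
        assert err.value.last_state is not None

    def test_matches_closed_form(self, small_regime_params):
        for p in small_regime_params:
            ode = integrate_to_steady_state(p, t_max=1e12)
            cf = solve_steady_state(p)
            diff = np.abs(ode.as_array() - cf.state.as_array())
            assert np.max(diff) < 1e-6 * p.W_T


class TestAttractorUniqueness:
    def test_initial_condition_independence(self, mixed_regime_params):
        # three conservation-compatible initial states per parameter set
        for p in mixed_regime_params[::2]:
            inits = [
                default_initial_state(p),
                CycleState(W=0.0, Wp=p.W_T, WK=0.0, WpP=0.0, K=p.K_T, P=p.P_T),
            ]
            c = min(p.W_T, p.K_T) / 2
            inits.append(CycleState(W=p.W_T - c, Wp=0.0, WK=c, WpP=0.0,
                                    K=p.K_T - c, P=p.P_T))
            finals = [integrate_to_steady_state(p, initial=s, t_max=1e12)
                      for s in inits]
            ref = finals[0].as_array()
            for other in finals[1:]:
                assert np.max(np.abs(other.as_array() - ref)) < 1e-5 * p.W_T


class TestTimeCourse:
    def test_positivity_and_terminal_state(self):
        p = make_cycle_parameters(5, 1, 2, 3, 0.5, 1, 1.0, 0.8, 0.6)
        times = np.linspace(0.0, 200.0, 101)
        traj = simulate_time_course(p, times)
        assert traj.shape == (101, 6)
        assert np.all(traj >= -1e-12 * p.W_T)
        cf = solve_steady_state(p)
        assert np.max(np.abs(traj[-1] - cf.state.as_array())) < 1e-6 * p.W_T

    def test_bad_time_grid_rejected(self):
        p = make_cycle_parameters(1, 1, 1, 1, 1, 1, 1, 1, 1)
        with pytest.raises(InvalidParameterError):
            simulate_time_course(p, np.array([1.0, 2.0]))
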