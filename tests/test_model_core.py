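"""Kinetic core: master-equation propagation, steady states, P_o arithmetic
and the Mendelian receptor-mixture utility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import channelkit as ck
from channelkit.model_core import (
    generator_matrix, _simulate_segment, R, O, B,
)

rates_st = st.builds(
    ck.RateSet,
    k_d=st.floats(0.0, 10.0), k_r=st.floats(0.01, 10.0),
    k_o=st.floats(0.0, 300.0), k_c=st.floats(1.0, 500.0),
    k_b=st.floats(0.0, 50.0), k_u=st.floats(0.0, 5.0),
)


def glu_protocol(dur=2.0, mk=0.0, tau=0.0):
    return ck.ApplicationProtocol(
        epochs=[{"t_start": 0.0, "t_end": dur, "glutamate": 1000.0, "mk801": mk}],
        exchange_tau=tau)


class TestSimulation:
    def test_two_state_equilibrium(self):
        occ = ck.simulate_occupancies(
            ck.RateSet(k_d=0, k_r=0, k_o=100, k_c=200),
            glu_protocol(), np.arange(0, 2, 1e-4))
        assert occ.p_O[-1] == pytest.approx(100 / 300, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rates=rates_st, mk=st.floats(0.0, 5.0), tau=st.floats(0.0, 0.03))
    def test_occupancy_conservation(self, rates, mk, tau):
        occ = ck.simulate_occupancies(rates, glu_protocol(mk=mk, tau=tau),
                                      np.arange(0, 0.5, 1e-3))
        total = occ.p.sum(axis=1)
        assert np.max(np.abs(total - 1.0)) < 1e-8
        assert occ.p.min() >= 0 and occ.p.max() <= 1

    def test_matches_matrix_exponential_oracle(self, wt_rates):
        t = np.arange(0, 1.0, 1e-3)
        occ = ck.simulate_occupancies(wt_rates, glu_protocol(mk=1.0), t)
        A = generator_matrix(wt_rates, 1.0)
        p0 = np.zeros(4); p0[R] = 1.0
        oracle = np.array([expm(A * tt) @ p0 for tt in t])
        assert np.max(np.abs(occ.p - oracle)) < 1e-8

    def test_blocked_occupancy_monotone_when_irreversible(self, wt_rates):
        occ = ck.simulate_occupancies(wt_rates, glu_protocol(mk=1.0, tau=0.012),
                                      np.arange(0, 2, 1e-4))
        assert np.all(np.diff(occ.p_B) >= -1e-12)

    def test_exchange_transient_ode_agrees_with_propagator(self, wt_rates):
        """The adaptive-ODE fast path and the exact piecewise propagator must
        agree through the solution-exchange transient."""
        t = np.arange(0, 0.6, 1e-4)
        p0 = np.zeros(4); p0[R] = 1.0
        a, _ = _simulate_segment(wt_rates, 0.0, 1.0, 0.012, t, p0, transient="expm")
        b, _ = _simulate_segment(wt_rates, 0.0, 1.0, 0.012, t, p0, transient="ode")
        assert np.max(np.abs(a - b)) < 1e-6

    def test_exchange_transient_matches_direct_ivp(self, wt_rates):
        """Independent check of the transient handling: integrate the
        time-dependent master equation directly."""
        tau, mk = 0.012, 1.0
        t = np.arange(0, 0.3, 1e-4)
        p0 = np.zeros(4); p0[R] = 1.0
        occ, _ = _simulate_segment(wt_rates, 0.0, mk, tau, t, p0, transient="expm")

        def rhs(tt, p):
            c = mk * (1 - np.exp(-tt / tau))
            return generator_matrix(wt_rates, c) @ p

        sol = solve_ivp(rhs, (0, t[-1]), p0, t_eval=t, rtol=1e-10, atol=1e-13)
        assert np.max(np.abs(occ - sol.y.T)) < 1e-6

    def test_current_zero_before_glutamate_onset(self, wt_rates):
        prot = ck.ApplicationProtocol(
            epochs=[{"t_start": 0.5, "t_end": 1.5, "glutamate": 1000.0}],
            exchange_tau=0.0)
        occ = ck.simulate_occupancies(wt_rates, prot, np.arange(0, 1.5, 1e-3))
        pre = occ.t < 0.5
        assert np.all(occ.p_O[pre] == 0) and np.all(occ.p_R[pre] == 1)

    def test_grid_validation(self, wt_rates):
        with pytest.raises(ck.ValidationError):
            ck.simulate_occupancies(wt_rates, glu_protocol(),
                                    np.array([0.0, 0.1, 0.15]))
        with pytest.raises(ck.ValidationError):
            ck.RateSet(k_d=-1.0)


class TestSteadyState:
    def test_two_state_limit(self):
        ss = ck.steady_state(ck.RateSet(k_d=0, k_r=0, k_o=100, k_c=200))
        assert ss.p_O == pytest.approx(100 / 300)

    def test_wt_closed_form_and_long_time_simulation(self):
        rates = ck.RateSet(k_d=0.17, k_r=0.69, k_o=27.8, k_c=200.0)
        ss = ck.steady_state(rates)
        expected = (27.8 / 200) / (1 + 0.17 / 0.69 + 27.8 / 200)
        assert ss.p_O == pytest.approx(expected, rel=1e-12)
        assert ss.p_O == pytest.approx(0.1003, abs=5e-4)
        occ = ck.simulate_occupancies(rates, glu_protocol(dur=60.0),
                                      np.arange(0, 60, 1e-2))
        assert occ.p_O[-1] == pytest.approx(ss.p_O, rel=1e-6)

    def test_irreversible_block_is_absorbing(self, wt_rates):
        ss = ck.steady_state(wt_rates, mk801=1.0)
        assert ss.absorbing and ss.p[B] == 1.0

    def test_reversible_block_detailed_balance(self):
        rates = ck.RateSet(k_d=0.2, k_r=0.5, k_o=30, k_c=200, k_b=25, k_u=0.5)
        ss = ck.steady_state(rates, mk801=1.0)
        A = generator_matrix(rates, 1.0)
        assert np.max(np.abs(A @ ss.p)) < 1e-12

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ck.DegenerateSchemeError):
            ck.steady_state(ck.RateSet(k_d=1.0, k_r=0.0, k_o=10, k_c=200))


class TestOpenProbability:
    @pytest.mark.parametrize("k_o,k_c,expected", [
        (200.0, 200.0, 50.0),
        (0.0, 200.0, 0.0),
        (23.46, 200.0, 10.5),
    ])
    def test_values(self, k_o, k_c, expected):
        assert ck.open_probability(k_o, k_c) == pytest.approx(expected, abs=5e-2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_o=st.floats(0.0, 1e4), k_c=st.floats(1e-3, 1e4))
    def test_bounds_and_monotonicity(self, k_o, k_c):
        po = ck.open_probability(k_o, k_c)
        assert 0 <= po < 100
        assert ck.open_probability(k_o + 1.0, k_c) > po

    def test_invalid_kc(self):
        with pytest.raises(ck.ValidationError):
            ck.open_probability(10.0, 0.0)


class TestMendelianActivity:
    @pytest.mark.parametrize("mode,expected", [
        ("recessive", 77.5), ("independent", 55.0), ("dominant", 32.5)])
    def test_heterozygote_mixture(self, mode, expected):
        assert ck.mendelian_activity(10.0, 1.0, mode) == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(po=st.floats(0.1, 100.0),
           mode=st.sampled_from(["recessive", "independent", "dominant"]))
    def test_no_defect_means_full_activity(self, po, mode):
        assert ck.mendelian_activity(po, po, mode) == pytest.approx(100.0)

    def test_unknown_mode(self):
        with pytest.raises(ck.ValidationError):
            ck.mendelian_activity(10.0, 1.0, "codominant")


class TestSerialization:
    def test_rateset_json_round_trip(self, wt_rates):
        assert ck.RateSet.from_json(wt_rates.to_json()) == wt_rates

    def test_protocol_json_round_trip(self):
        prot = ck.ApplicationProtocol(
            epochs=[{"t_start": 0.0, "t_end": 1.0, "glutamate": 1000.0},
                    {"t_start": 1.0, "t_end": 2.0, "glutamate": 1000.0, "mk801": 1.0}],
            exchange_tau=0.012)
        back = ck.ApplicationProtocol.from_json(prot.to_json())
        assert back.to_dict() == prot.to_dict()

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.ApplicationProtocol(epochs=[
                {"t_start": 0.0, "t_end": 1.0}, {"t_start": 0.5, "t_end": 2.0}])
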