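"""Deterministic two-compartment exchange model and closed-form estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctckinetics.model import (
    LN2,
    ExchangeParams,
    SteadyStateRates,
    SystemState,
    estimate_generation_rate,
    estimate_half_life,
    integrate,
    ode_rhs,
    steady_state_counts,
    steady_state_rates,
)


class TestParams:
    def test_half_life_clearance_consistency(self):
        p = ExchangeParams(r_gen=10.0, t_half_s=90.0)
        assert p.k_clear * (p.t_half_s / 60.0) == pytest.approx(LN2, rel=1e-12)
        p2 = ExchangeParams(r_gen=10.0, k_clear=p.k_clear)
        assert p2.t_half_s == pytest.approx(90.0, rel=1e-12)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ExchangeParams(r_gen=1.0, t_half_s=90.0, k_clear=1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_gen": -1.0, "t_half_s": 90.0},
            {"r_gen": 1.0, "t_half_s": -90.0},
            {"r_gen": 1.0, "t_half_s": 90.0, "V": 0.0},
            {"r_gen": 1.0, "t_half_s": 90.0, "duration": 0.0},
            {"r_gen": 1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExchangeParams(**kwargs)

    def test_fast_pump_warns_but_does_not_fail(self):
        with pytest.warns(UserWarning, match="well-mixed"):
            ExchangeParams(r_gen=1.0, t_half_s=90.0, V=1.0, Q=2000.0)


class TestOdeRhs:
    def test_empty_system_stays_empty(self):
        p = ExchangeParams(r_gen=0.0, t_half_s=90.0)
        assert ode_rhs(SystemState(0.0, 0.0), p) == (0.0, 0.0)

    def test_generation_is_the_only_inflow(self):
        p = ExchangeParams(r_gen=100.0, t_half_s=90.0)
        assert ode_rhs(SystemState(0.0, 0.0), p) == (100.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SystemState(-1.0, 0.0)

    def test_vanishes_at_closed_form_steady_state(self, sclc_params):
        n1, n2 = steady_state_counts(sclc_params)
        dn1, dn2 = ode_rhs(SystemState(n1, n2), sclc_params)
        assert abs(dn1) < 1e-9 * sclc_params.r_gen
        assert abs(dn2) < 1e-9 * sclc_params.r_gen


class TestSteadyState:
    @settings(max_examples=100, derandomize=True)
    @given(
        r_gen=st.floats(1e-2, 1e4),
        t_half_s=st.floats(5.0, 2000.0),
        V=st.floats(0.5, 3.0),
        Q=st.floats(5.0, 500.0),
    )
    def test_estimator_round_trip(self, r_gen, t_half_s, V, Q):
        """Feeding the closed-form steady-state rates back through the
        estimators recovers r_gen and t_half to machine precision."""
        p = ExchangeParams(r_gen=r_gen, t_half_s=t_half_s, V=V, Q=Q)
        rates = steady_state_rates(p)
        assert estimate_generation_rate(rates) == pytest.approx(r_gen, rel=1e-12)
        assert estimate_half_life(rates, V=V, Q=Q) == pytest.approx(
            t_half_s, rel=1e-12
        )

    def test_linearity_in_generation_rate(self, sclc_params):
        r = steady_state_rates(sclc_params)
        p2 = ExchangeParams(
            r_gen=2 * sclc_params.r_gen,
            t_half_s=sclc_params.t_half_s,
            V=sclc_params.V,
            Q=sclc_params.Q,
        )
        r2 = steady_state_rates(p2)
        assert r2.r1 == pytest.approx(2 * r.r1, rel=1e-12)
        assert r2.r2 == pytest.approx(2 * r.r2, rel=1e-12)
        assert r2.ratio == pytest.approx(r.ratio, rel=1e-12)

    def test_infinite_mixing_equalizes_rates(self):
        with pytest.warns(UserWarning):  # pump faster than blood turnover
            p = ExchangeParams(r_gen=100.0, t_half_s=90.0, V=1.75, Q=1e9)
        assert steady_state_rates(p).ratio == pytest.approx(1.0, abs=1e-6)

    def test_return_ratio_matches_long_horizon_integration(self):
        """r2/r1 ~ 0.069 at t_half = 90 s, checked against brute-force ODE."""
        p = ExchangeParams(
            r_gen=100.0, t_half_s=90.0, V=1.75, Q=60.0, transport_delay=0.0,
            duration=240.0,
        )
        rates = steady_state_rates(p)
        assert rates.r2 / rates.r1 == pytest.approx(0.069, abs=0.002)
        traj = integrate(p)
        assert traj.r2[-1] / traj.r1[-1] == pytest.approx(
            rates.r2 / rates.r1, rel=1e-8
        )

    def test_no_steady_state_without_clearance_or_flow(self):
        p = ExchangeParams(r_gen=1.0, t_half_s=90.0, Q=0.0)
        with pytest.raises(ValueError, match="Q > 0"):
            steady_state_rates(p)
        with pytest.raises(ValueError, match="r_gen > 0"):
            steady_state_rates(ExchangeParams(r_gen=0.0, t_half_s=90.0))


class TestEstimators:
    def test_generation_rate_arithmetic(self):
        assert estimate_generation_rate(SteadyStateRates(10.0, 5.0)) == 15.0

    def test_equal_rates_imply_no_generation(self):
        assert estimate_generation_rate(SteadyStateRates(3.0, 3.0)) == 0.0

    def test_zero_return_rate_is_undefined(self):
        with pytest.raises(ValueError, match="r2 = 0"):
            estimate_generation_rate(SteadyStateRates(1.0, 0.0))

    def test_inverted_rates_flagged_non_physical(self):
        with pytest.warns(UserWarning, match="non-physical"):
            assert estimate_generation_rate(SteadyStateRates(1.0, 2.0)) < 0

    def test_half_life_unit_ratio(self):
        # r1/r2 = 2 with V/Q = 1 min gives t_half = ln(2) min
        t = estimate_half_life(SteadyStateRates(2.0, 1.0), V=1.0, Q=1000.0)
        assert t == pytest.approx(60.0 * LN2, rel=1e-12)

    def test_half_life_diverges_as_rates_equalize(self):
        eps = np.logspace(-6, -1, 10)[::-1]
        t = [estimate_half_life(SteadyStateRates(1.0 + e, 1.0)) for e in eps]
        assert np.all(np.diff(t) > 0)  # smaller eps -> longer half-life

    def test_half_life_out_of_model_inputs_rejected(self):
        for r1, r2 in [(1.0, 1.0), (1.0, 2.0), (1.0, 0.0)]:
            with pytest.raises(ValueError, match="r1 > r2 > 0"):
                estimate_half_life(SteadyStateRates(r1, r2))


class TestIntegrate:
    def test_pure_decay_closed_form(self):
        """With no generation and no pump flow, the TBM count decays as
        N0 exp(-K t)."""
        p = ExchangeParams(
            r_gen=0.0, t_half_s=120.0, Q=0.0, transport_delay=0.0, duration=20.0
        )
        t = np.linspace(0.0, 20.0, 41)
        traj = integrate(p, SystemState(1000.0, 0.0), t)
        np.testing.assert_allclose(
            traj.n1, 1000.0 * np.exp(-p.k_clear * t), rtol=1e-7
        )
        np.testing.assert_allclose(traj.n2, 0.0, atol=1e-7)

    def test_growth_to_steady_state_closed_form_q0(self):
        """With Q = 0 the TBM trajectory is r_gen/K (1 - exp(-K t))."""
        p = ExchangeParams(
            r_gen=50.0, t_half_s=90.0, Q=0.0, transport_delay=0.0, duration=30.0
        )
        t = np.linspace(0.0, 30.0, 31)
        traj = integrate(p, t_grid=t)
        expected = p.r_gen / p.k_clear * (1.0 - np.exp(-p.k_clear * t))
        np.testing.assert_allclose(traj.n1, expected, rtol=1e-7, atol=1e-9)

    def test_long_horizon_convergence_to_closed_form(self, sclc_params):
        p = ExchangeParams(
            r_gen=sclc_params.r_gen,
            t_half_s=sclc_params.t_half_s,
            transport_delay=0.0,
            duration=20.0 / sclc_params.k_clear,
        )
        traj = integrate(p)
        n1_ss, n2_ss = steady_state_counts(p)
        assert traj.n1[-1] == pytest.approx(n1_ss, rel=1e-6)
        assert traj.n2[-1] == pytest.approx(n2_ss, rel=1e-6)

    @pytest.mark.parametrize("delay", [0.0, 2.0])
    def test_conservation_of_cells(self, delay):
        """Every generated cell is circulating, in transit, or cleared."""
        p = ExchangeParams(
            r_gen=100.0, t_half_s=90.0, transport_delay=delay, duration=120.0
        )
        traj = integrate(p)
        generated = p.r_gen * traj.t
        accounted = traj.n1 + traj.n2 + traj.in_transit + traj.cum_cleared
        np.testing.assert_allclose(accounted[1:], generated[1:], rtol=1e-6)

    def test_return_fraction_in_observed_range(self):
        """4 h of exchange at t_half = 90 s returns 3-7% of transferred CTCs."""
        p = ExchangeParams(
            r_gen=100.0, t_half_s=90.0, V=1.75, Q=60.0, transport_delay=0.0,
            duration=240.0,
        )
        frac = integrate(p).return_fraction()
        assert 0.03 <= frac <= 0.07

    def test_delay_shifts_detected_counts(self):
        p = ExchangeParams(
            r_gen=100.0, t_half_s=90.0, transport_delay=2.0, duration=60.0
        )
        traj = integrate(p)
        # detections lag samplings by the transit time and never exceed them
        assert traj.cum_detected1[-1] < traj.cum_sampled1[-1]
        i = np.searchsorted(traj.t, 2.0)
        np.testing.assert_allclose(
            traj.cum_detected1[i:], traj.cum_sampled1[: len(traj.t) - i], rtol=1e-6
        )

    def test_bad_grid_rejected(self):
        p = ExchangeParams(r_gen=1.0, t_half_s=90.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            integrate(p, t_grid=[0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="start at"):
            integrate(p, SystemState(0.0, 0.0, t=5.0), t_grid=[0.0, 10.0])
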