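import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from delayosc import (
    HistoryFunction,
    LevelsError,
    ReductionConfigError,
    SwitchConfig,
    boundary_curves,
    calibrate_to_equilibrium,
    first_order_period,
    first_order_switch_points,
    flow_map,
    integrate_dde,
    period_amplitude,
    reduction_error_report,
    self_consistent_levels,
    simulate_first_order,
    simulate_second_order,
    switch_points_by_quadrature,
)


@pytest.fixture(scope="module")
def nonsat20():
    return calibrate_to_equilibrium("monotonic", "non_saturable", n=20, tau=5.0)


@pytest.fixture(scope="module")
def sat20():
    return calibrate_to_equilibrium("monotonic", "saturable", n=20, tau=5.0)


class TestFlowMap:
    def test_linear_degradation_closed_form(self, nonsat20):
        # x' = 2 - x from x0 = 1 for ln 2:  2 - e^(-ln 2) = 1.5
        assert flow_map(nonsat20, 2.0, 1.0, math.log(2)) == pytest.approx(1.5)

    def test_zero_duration_identity(self, sat20):
        assert flow_map(sat20, 0.3, 0.77, 0.0) == 0.77

    @pytest.mark.parametrize("s,x0,dur", [(1.0, 0.2, 2.0), (0.3, 1.5, 3.0),
                                          (0.0, 1.0, 1.5), (2.5, 0.5, 1.0)])
    def test_saturable_matches_high_accuracy_ode(self, sat20, s, x0, dur):
        got = flow_map(sat20, s, x0, dur)
        sol = solve_ivp(
            lambda t, y: [s - float(sat20.degradation(max(y[0], 0.0)))],
            (0, dur), [x0], rtol=1e-12, atol=1e-14, dense_output=True,
        )
        assert got == pytest.approx(float(sol.y[0][-1]), abs=1e-8)


class TestSwitchPoints:
    def test_zero_delay_collapses_to_equilibrium(self, nonsat20):
        pts = first_order_switch_points(
            nonsat20.with_tau(0.0), SwitchConfig.from_extremes(nonsat20)
        )
        assert pts.X_A == pytest.approx(1.0) and pts.X_B == pytest.approx(1.0)

    @pytest.mark.parametrize("fixture", ["nonsat20", "sat20"])
    def test_integral_equation_agrees_with_flow_map(self, fixture, request):
        spec = request.getfixturevalue(fixture)
        sw = SwitchConfig.from_extremes(spec)
        pts = first_order_switch_points(spec, sw)
        ptq = switch_points_by_quadrature(spec, sw)
        assert pts.X_A == pytest.approx(ptq.X_A, abs=1e-8)
        assert pts.X_B == pytest.approx(ptq.X_B, abs=1e-8)

    def test_points_straddle_equilibrium_and_widen_with_delay(self, nonsat20):
        sw = SwitchConfig.from_extremes(nonsat20)
        prev_a, prev_b = 1.0, 1.0
        for tau in (1.0, 3.0, 6.0):
            pts = first_order_switch_points(nonsat20.with_tau(tau), sw)
            assert pts.X_B < 1.0 < pts.X_A
            assert pts.X_A > prev_a and pts.X_B < prev_b
            prev_a, prev_b = pts.X_A, pts.X_B

    def test_levels_not_straddling_equilibrium_rejected(self, nonsat20):
        with pytest.raises(ReductionConfigError):
            first_order_switch_points(
                nonsat20, SwitchConfig(s_high=0.9, s_low=0.0)
            )

    def test_non_monotonic_models_not_reducible(self):
        spec = calibrate_to_equilibrium("non_monotonic", "non_saturable", n=10, tau=3.0)
        with pytest.raises(ReductionConfigError):
            first_order_switch_points(spec, SwitchConfig(s_high=2.0, s_low=0.0))


class TestSelfConsistentLevels:
    def test_levels_interleave_equilibrium_rate(self, nonsat20):
        sw = self_consistent_levels(nonsat20)
        f_star = float(nonsat20.synthesis(1.0))
        assert sw.s_low < f_star < sw.s_high

    def test_two_cycle_residual(self, nonsat20):
        sw = self_consistent_levels(nonsat20)
        h = lambda r: float(nonsat20.synthesis(r / nonsat20.gamma))
        assert abs(sw.s_high - h(sw.s_low)) < 1e-9
        assert abs(sw.s_low - h(sw.s_high)) < 1e-9

    def test_levels_approach_extremes_as_n_grows(self):
        gaps = []
        for n in (5, 10, 20, 40):
            spec = calibrate_to_equilibrium("monotonic", "non_saturable", n=n, tau=5.0)
            sw = self_consistent_levels(spec)
            gaps.append((spec.beta - sw.s_high) + sw.s_low)
        assert all(g > 0 for g in gaps)
        assert np.all(np.diff(gaps) < 0)
        assert gaps[-1] < 1e-9

    def test_shallow_synthesis_has_no_two_cycle(self):
        spec = calibrate_to_equilibrium("monotonic", "non_saturable", n=1.5, tau=5.0)
        with pytest.raises(LevelsError):
            self_consistent_levels(spec)

    def test_saturable_case_rejected(self, sat20):
        with pytest.raises(ReductionConfigError):
            self_consistent_levels(sat20)


class TestFirstOrder:
    @pytest.mark.parametrize("fixture", ["nonsat20", "sat20"])
    def test_simulated_period_matches_closed_form(self, fixture, request):
        spec = request.getfixturevalue(fixture)
        sw = SwitchConfig.from_extremes(spec)
        traj = simulate_first_order(spec, sw, t_end=80.0, dt=1e-3)
        assert traj.event_period() == pytest.approx(
            first_order_period(spec, sw), rel=1e-3
        )

    def test_period_independent_of_cooperativity(self):
        periods = []
        for n in (10, 20, 40):
            spec = calibrate_to_equilibrium("monotonic", "non_saturable", n=n, tau=5.0)
            periods.append(first_order_period(spec, SwitchConfig.from_extremes(spec)))
        assert np.ptp(periods) < 1e-9 * periods[0]

    def test_period_underestimates_the_delay_model(self, nonsat20):
        ts = integrate_dde(nonsat20, HistoryFunction(value=1.1), 400.0, 1e-3)
        dde_period = period_amplitude(ts, level=1.0).period
        p1 = first_order_period(nonsat20, SwitchConfig.from_extremes(nonsat20))
        assert p1 < dde_period

    def test_trajectory_periodic_after_first_event(self, nonsat20):
        sw = SwitchConfig.from_extremes(nonsat20)
        traj = simulate_first_order(nonsat20, sw, t_end=120.0, dt=1e-3)
        gaps = np.diff(traj.switch_times[::2])
        assert np.ptp(gaps) < 1e-6 * gaps.mean()


class TestBoundaryCurves:
    def test_zero_delay_curves_are_the_diagonal(self, nonsat20):
        lower, upper = boundary_curves(
            nonsat20.with_tau(0.0), SwitchConfig.from_extremes(nonsat20)
        )
        c = np.linspace(0.2, 1.8, 7)
        np.testing.assert_allclose(lower(c), c, atol=1e-12)
        np.testing.assert_allclose(upper(c), c, atol=1e-12)

    @pytest.mark.parametrize("fixture", ["nonsat20", "sat20"])
    def test_lower_left_of_upper(self, fixture, request):
        spec = request.getfixturevalue(fixture)
        lower, upper = boundary_curves(spec, SwitchConfig.from_extremes(spec))
        c = np.linspace(lower.u2[0], lower.u2[-1], 101)
        assert np.all(lower(c) < upper(c))

    def test_non_saturable_closed_form(self, nonsat20):
        sw = SwitchConfig.from_extremes(nonsat20)
        lower, upper = boundary_curves(nonsat20, sw)
        g, tau = nonsat20.gamma, nonsat20.tau
        c = np.linspace(lower.u2[0], lower.u2[-1], 50)
        for curve, s in ((lower, sw.s_low), (upper, sw.s_high)):
            exact = s / g + (c - s / g) * np.exp(-g * tau)
            np.testing.assert_allclose(curve(c), exact, atol=1e-8)

    def test_delay_trajectory_respects_curves(self, nonsat20):
        lower, upper = boundary_curves(nonsat20, SwitchConfig.from_extremes(nonsat20))
        ts = integrate_dde(nonsat20, HistoryFunction(value=1.1), 350.0, 1e-3)
        d = int(round(nonsat20.tau / ts.dt))
        x_now = ts.values[ts.transient_end :]
        x_del = ts.values[ts.transient_end - d : len(ts.values) - d]
        assert np.all(x_now >= lower(x_del) - 1e-3)
        assert np.all(x_now <= upper(x_del) + 1e-3)


class TestSecondOrder:
    @pytest.mark.parametrize("fixture", ["nonsat20", "sat20"])
    def test_sustained_periodic_orbit(self, fixture, request):
        spec = request.getfixturevalue(fixture)
        sw = (
            self_consistent_levels(spec)
            if spec.degradation_kind.value == "non_saturable"
            else SwitchConfig.from_extremes(spec)
        )
        traj = simulate_second_order(spec, sw, t_end=150.0, dt=1e-3)
        assert len(traj.switch_times) >= 8
        assert not traj.chattering
        stats = period_amplitude(traj.to_timeseries(transient=60.0), level=1.0)
        assert stats.cv < 0.01

    def test_period_tracks_delay_dependence(self, nonsat20):
        # unlike the first-order reduction, the period follows tau with the
        # full model's slope
        sw_by_tau = {}
        for tau in (4.0, 6.0):
            spec = nonsat20.with_tau(tau)
            traj = simulate_second_order(
                spec, self_consistent_levels(spec), t_end=150.0, dt=1e-3
            )
            sw_by_tau[tau] = period_amplitude(
                traj.to_timeseries(transient=60.0), level=1.0
            ).period
        assert sw_by_tau[6.0] - sw_by_tau[4.0] == pytest.approx(2 * 2.0, rel=0.15)


class TestErrorReport:
    def test_second_order_beats_first_order_at_large_n(self, nonsat20, sat20):
        report = reduction_error_report([nonsat20, sat20], t_end=300.0)
        for _, grp in report.groupby(["synthesis", "degradation"]):
            e1 = abs(grp[grp.order == 1].period_rel_err.iloc[0])
            e2 = abs(grp[grp.order == 2].period_rel_err.iloc[0])
            assert e2 < e1
            assert e2 < 0.10

    def test_report_deterministic(self, nonsat20):
        a = reduction_error_report([nonsat20], t_end=250.0)
        b = reduction_error_report([nonsat20], t_end=250.0)
        assert a.equals(b)
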