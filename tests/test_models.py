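import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delayosc import (
    CalibrationError,
    Equilibrium,
    ModelSpec,
    calibrate_to_equilibrium,
    evaluate_rates,
    find_equilibria,
    linearize,
    synthesis_extremes,
)

KINDS = [
    ("monotonic", "saturable"),
    ("monotonic", "non_saturable"),
    ("non_monotonic", "saturable"),
    ("non_monotonic", "non_saturable"),
]


def spec_of(syn, deg, beta=2.0, gamma=1.0, n=4.0, tau=1.0):
    return ModelSpec(syn, deg, beta, gamma, n, tau)


class TestRates:
    def test_monotonic_synthesis_vanishes_at_high_repressor(self):
        spec = spec_of("monotonic", "non_saturable")
        s, _ = evaluate_rates(spec, x_delayed=1e6, x_now=1.0)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_non_monotonic_synthesis_vanishes_at_zero(self):
        spec = spec_of("non_monotonic", "non_saturable")
        s, _ = evaluate_rates(spec, x_delayed=0.0, x_now=1.0)
        assert s == 0.0

    def test_linear_degradation(self):
        spec = spec_of("monotonic", "non_saturable", gamma=0.7)
        _, g = evaluate_rates(spec, x_delayed=1.0, x_now=3.0)
        assert g == pytest.approx(0.7 * 3.0)

    @pytest.mark.parametrize("syn,deg", KINDS)
    def test_rates_nonnegative_and_shapes(self, syn, deg):
        spec = spec_of(syn, deg)
        xs = np.linspace(0, 10, 50)
        f = spec.synthesis(xs)
        g = spec.degradation(xs)
        assert np.all(f >= 0) and np.all(g >= 0)
        if syn == "monotonic":
            assert np.all(np.diff(f) < 0), "repressor strictly decreasing"
        else:
            peak = np.argmax(f)
            assert 0 < peak < len(xs) - 1, "rises then falls"

    def test_negative_concentration_rejected(self):
        spec = spec_of("monotonic", "saturable")
        with pytest.raises(ValueError):
            evaluate_rates(spec, -0.1, 1.0)


class TestEquilibria:
    def test_monotonic_nonsaturable_unit_equilibrium(self):
        spec = spec_of("monotonic", "non_saturable", beta=2.0, gamma=1.0, n=7)
        eqs = find_equilibria(spec)
        assert len(eqs) == 1
        assert eqs[0].x_star == pytest.approx(1.0, abs=1e-10)
        assert eqs[0].residual < 1e-10

    def test_non_monotonic_nonsaturable_equilibria_zero_and_one(self):
        spec = spec_of("non_monotonic", "non_saturable", beta=2.0, gamma=1.0, n=4)
        xs = [e.x_star for e in find_equilibria(spec)]
        assert xs[0] == 0.0
        assert xs[-1] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("deg", ["saturable", "non_saturable"])
    def test_trivial_equilibrium_always_present_for_non_monotonic(self, deg):
        spec = spec_of("non_monotonic", deg, beta=0.6, gamma=1.3, n=3)
        eqs = find_equilibria(spec)
        assert eqs[0].is_trivial and eqs[0].x_star == 0.0

    @pytest.mark.parametrize("deg", ["saturable", "non_saturable"])
    def test_monotonic_unique_positive_equilibrium_on_grid(self, deg):
        for beta in (0.5, 2.0, 8.0):
            for gamma in (0.5, 1.0, 3.0):
                for n in (1.0, 4.0, 12.0):
                    spec = spec_of("monotonic", deg, beta, gamma, n)
                    positive = [e for e in find_equilibria(spec) if not e.is_trivial]
                    assert len(positive) == 1, (beta, gamma, n)


class TestCalibration:
    def test_monotonic_nonsaturable_beta(self):
        spec = calibrate_to_equilibrium(
            "monotonic", "non_saturable", n=7, tau=1.0, x_target=1.0, gamma=1.0
        )
        assert spec.beta == pytest.approx(2.0)

    def test_monotonic_saturable_beta(self):
        spec = calibrate_to_equilibrium(
            "monotonic", "saturable", n=7, tau=1.0, x_target=1.0, gamma=1.0
        )
        assert spec.beta == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        gamma=st.floats(0.1, 10.0),
        c=st.floats(0.5, 5.0),
        n=st.floats(1.0, 20.0),
        kinds=st.sampled_from(KINDS),
    )
    def test_beta_scales_linearly_with_gamma(self, gamma, c, n, kinds):
        syn, deg = kinds
        b1 = calibrate_to_equilibrium(syn, deg, n, 0.0, 1.3, gamma).beta
        b2 = calibrate_to_equilibrium(syn, deg, n, 0.0, 1.3, c * gamma).beta
        assert b2 == pytest.approx(c * b1, rel=1e-12)

    @pytest.mark.parametrize("syn,deg", KINDS)
    def test_round_trip_recovers_target(self, syn, deg):
        for x_target in (0.4, 1.0, 2.5):
            spec = calibrate_to_equilibrium(syn, deg, 6.0, 1.0, x_target, 1.5)
            xs = [e.x_star for e in find_equilibria(spec) if not e.is_trivial]
            assert min(abs(x - x_target) for x in xs) < 1e-8

    def test_invalid_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_to_equilibrium("monotonic", "saturable", 4, 1.0, -1.0, 1.0)


class TestLinearize:
    def test_nonsaturable_b_is_gamma(self, mono_nonsat_spec):
        eq = find_equilibria(mono_nonsat_spec)[0]
        co = linearize(mono_nonsat_spec, eq)
        assert co.b == mono_nonsat_spec.gamma

    def test_monotonic_a_negative(self, mono_sat_spec):
        eq = find_equilibria(mono_sat_spec)[0]
        assert linearize(mono_sat_spec, eq).a < 0

    def test_non_monotonic_closed_form(self):
        spec = spec_of("non_monotonic", "non_saturable", beta=2.0, gamma=1.0, n=4)
        eq = [e for e in find_equilibria(spec) if not e.is_trivial][0]
        co = linearize(spec, eq)
        assert co.a == pytest.approx(spec.beta * (2 - spec.n) / 4, abs=1e-9)

    def test_trivial_equilibrium_flagged(self):
        spec = spec_of("non_monotonic", "non_saturable")
        with pytest.warns(UserWarning, match="positive"):
            co = linearize(spec, Equilibrium(0.0, True, 0.0))
        assert co.a > 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        kinds=st.sampled_from(KINDS),
        beta=st.floats(0.5, 5.0),
        gamma=st.floats(0.3, 3.0),
        n=st.floats(1.5, 15.0),
    )
    def test_derivatives_match_finite_differences(self, kinds, beta, gamma, n):
        syn, deg = kinds
        spec = spec_of(syn, deg, beta, gamma, n)
        positive = [e for e in find_equilibria(spec) if not e.is_trivial]
        if not positive:
            return
        eq = positive[0]
        co = linearize(spec, eq)
        h = 1e-6 * max(1.0, eq.x_star)
        fd_a = (spec.synthesis(eq.x_star + h) - spec.synthesis(eq.x_star - h)) / (2 * h)
        fd_b = (
            spec.degradation(eq.x_star + h) - spec.degradation(eq.x_star - h)
        ) / (2 * h)
        assert co.a == pytest.approx(fd_a, rel=1e-5, abs=1e-8)
        assert co.b == pytest.approx(fd_b, rel=1e-5, abs=1e-8)


class TestSynthesisExtremes:
    def test_monotonic_range_is_zero_to_beta(self):
        spec = spec_of("monotonic", "saturable", beta=2.0)
        assert synthesis_extremes(spec) == (0.0, 2.0)

    def test_span_equals_beta_and_scales(self):
        for beta in (1.0, 3.0):
            lo, hi = synthesis_extremes(spec_of("monotonic", "non_saturable", beta=beta))
            assert hi - lo == pytest.approx(beta)

    def test_non_monotonic_peak_bounds_samples(self):
        spec = spec_of("non_monotonic", "saturable", beta=2.0, n=6)
        lo, hi = synthesis_extremes(spec)
        xs = np.linspace(0, 50, 20000)
        f = spec.synthesis(xs)
        assert lo == 0.0
        assert f.max() <= hi + 1e-9
        assert hi == pytest.approx(f.max(), rel=1e-4)
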