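"""Cumulative-hazard computation and closed-form vs numeric inversion.

The integral-defined cumulative hazard is the ground truth here: quadrature
of h0(s)*exp(beta_t*z(s)+eta) checks `cumulative_hazard_tvc`, and the
bracketed root-finder `invert_numeric` serves as the oracle for every closed
form.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from tvcsim import (
    BaselineHazard,
    LinearDoseTrajectory,
    PiecewiseBinaryTrajectory,
    SingleSwitchTrajectory,
    SubjectSpec,
    TimeInvariantTrajectory,
    UnsupportedInversionError,
    cumulative_hazard_powerscale_dose,
    cumulative_hazard_tvc,
    draw_event_times,
    invert_closed_form,
    invert_linear_dose_weibull_powerscale,
    invert_numeric,
    simulate_invariant_time,
)
from tvcsim.engine import _invert_linear_dose_weibull


def quad_cumhaz(b, s, t):
    """Direct quadrature of the hazard integrand: the definitional H."""
    def integrand(v):
        if v <= 0:
            return 0.0
        return b.hazard(v) * math.exp(s.beta_t * s.trajectory.value_at(v) + s.eta)

    pieces = [0.0]
    if hasattr(s.trajectory, "segments"):
        pieces += [a for a, _ in s.trajectory.segments() if 0 < a < t]
    pieces.append(t)
    return sum(
        integrate.quad(integrand, a, bb, limit=200)[0] for a, bb in zip(pieces, pieces[1:])
    )


class TestCumulativeHazard:
    def test_single_switch_exponential_example(self):
        b = BaselineHazard.exponential(1.0)
        s = SubjectSpec(0.0, math.log(2), SingleSwitchTrajectory(1.0))
        # lam*t0 + 2*lam*(t-t0) = 1 + 2
        assert cumulative_hazard_tvc(b, s, 2.0) == pytest.approx(3.0, rel=1e-12)
        assert cumulative_hazard_tvc(b, s, 2.0) == pytest.approx(quad_cumhaz(b, s, 2.0), rel=1e-10)

    def test_pre_switch_weibull_example(self):
        b = BaselineHazard.weibull(0.001, 0.6)
        s = SubjectSpec(0.0, 0.5, SingleSwitchTrajectory(100.0))
        expected = 0.001 * 100**0.6
        assert cumulative_hazard_tvc(b, s, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_beta_t_reduces_to_scaled_baseline(self, baseline):
        eta = 0.4
        for traj in (
            SingleSwitchTrajectory(2.0),
            PiecewiseBinaryTrajectory((1.0, 3.0)),
            TimeInvariantTrajectory(7.0),
            LinearDoseTrajectory(0.3),
        ):
            s = SubjectSpec(eta, 0.0, traj)
            for t in (0.0, 0.5, 4.0):
                assert cumulative_hazard_tvc(baseline, s, t) == pytest.approx(
                    math.exp(eta) * baseline.cumulative_hazard(t), rel=1e-10, abs=1e-300
                )

    @pytest.mark.parametrize(
        "b",
        [
            BaselineHazard.exponential(0.3),
            BaselineHazard.gompertz(0.2, 0.1),
            BaselineHazard.weibull(0.8, 0.7),
            BaselineHazard.weibull(0.05, 1.8),
        ],
        ids=lambda b: b.family + str(b.lam),
    )
    @pytest.mark.parametrize("beta_t", [-0.6, 0.0, 0.4])
    def test_linear_dose_matches_quadrature(self, b, beta_t):
        s = SubjectSpec(0.2, beta_t, LinearDoseTrajectory(0.5))
        for t in (0.3, 1.0, 4.0):
            assert cumulative_hazard_tvc(b, s, t) == pytest.approx(
                quad_cumhaz(b, s, t), rel=1e-8
            )

    def test_piecewise_matches_quadrature(self, baseline):
        s = SubjectSpec(-0.3, 0.8, PiecewiseBinaryTrajectory((0.7, 2.1, 3.3)))
        for t in (0.5, 2.0, 6.0):
            assert cumulative_hazard_tvc(baseline, s, t) == pytest.approx(
                quad_cumhaz(baseline, s, t), rel=1e-9
            )

    def test_nondecreasing_and_zero_at_origin(self, baseline):
        s = SubjectSpec(0.1, -0.9, PiecewiseBinaryTrajectory((1.0, 2.5)))
        assert cumulative_hazard_tvc(baseline, s, 0.0) == 0.0
        grid = np.linspace(0.0, 8.0, 60)
        vals = [cumulative_hazard_tvc(baseline, s, t) for t in grid]
        assert all(b2 >= b1 for b1, b2 in zip(vals, vals[1:]))


class TestClosedFormInversion:
    def test_single_switch_branches(self):
        b = BaselineHazard.exponential(1.0)
        s = SubjectSpec(0.0, math.log(2), SingleSwitchTrajectory(1.0))
        assert invert_closed_form(b, s, 0.5) == pytest.approx(0.5, rel=1e-12)
        assert invert_closed_form(b, s, 2.0) == pytest.approx(1.5, rel=1e-12)
        for target in (0.5, 2.0):
            assert invert_closed_form(b, s, target) == pytest.approx(
                invert_numeric(b, s, target), rel=1e-10
            )

    def test_breakpoint_tie_goes_to_later_interval(self):
        b = BaselineHazard.exponential(1.0)
        s = SubjectSpec(0.0, math.log(2), SingleSwitchTrajectory(1.0))
        # H(t0) = 1 exactly: the switch instant belongs to the treated state
        assert invert_closed_form(b, s, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_round_trip_on_log_grid(self, baseline):
        s = SubjectSpec(0.3, -0.8, PiecewiseBinaryTrajectory((0.5, 1.5, 4.0)))
        bound = 0.99 * cumulative_hazard_tvc(baseline, s, 1e9)
        for h in np.geomspace(1e-6, 5.0, 25):
            if h >= bound:
                continue
            t = invert_closed_form(baseline, s, h)
            assert cumulative_hazard_tvc(baseline, s, t) == pytest.approx(h, rel=1e-8)

    def test_never_event_when_total_hazard_saturates(self):
        b = BaselineHazard.gompertz(0.2, -0.1)  # total baseline hazard 2
        s = SubjectSpec(0.0, -1.0, SingleSwitchTrajectory(1.0))
        bound = cumulative_hazard_tvc(b, s, 1e12)
        assert invert_closed_form(b, s, bound * 1.01) == math.inf
        assert invert_numeric(b, s, bound * 1.01) == math.inf
        assert invert_closed_form(b, s, bound * 0.5) < math.inf

    def test_linear_dose_exponential_analytic(self):
        # H(T) = 0.5*(e^T - 1) = 1  =>  T = log 3
        b = BaselineHazard.exponential(0.5)
        s = SubjectSpec(0.0, 1.0, LinearDoseTrajectory(1.0))
        assert invert_closed_form(b, s, 1.0) == pytest.approx(math.log(3.0), rel=1e-12)
        assert invert_numeric(b, s, 1.0) == pytest.approx(math.log(3.0), rel=1e-10)

    def test_linear_dose_negative_effect_saturates(self):
        b = BaselineHazard.exponential(0.5)
        s = SubjectSpec(0.0, -1.0, LinearDoseTrajectory(1.0))  # H_inf = 0.5
        assert invert_closed_form(b, s, 0.6) == math.inf
        assert invert_closed_form(b, s, 0.4) < math.inf

    def test_weibull_linear_dose_has_no_closed_form(self):
        b = BaselineHazard.weibull(0.001, 0.6)
        s = SubjectSpec(0.0, 0.5, LinearDoseTrajectory(0.01))
        with pytest.raises(UnsupportedInversionError):
            invert_closed_form(b, s, 1.0)

    @pytest.mark.parametrize("beta_t", [-0.4, 0.4])
    def test_weibull_linear_dose_fast_inverse_matches_oracle(self, beta_t):
        b = BaselineHazard.weibull(0.02, 0.7)
        s = SubjectSpec(0.3, beta_t, LinearDoseTrajectory(0.05))
        for target in (0.01, 0.3, 1.2):
            fast = _invert_linear_dose_weibull(b, s, target)
            slow = invert_numeric(b, s, target)
            if math.isinf(fast):
                assert math.isinf(slow)
            else:
                assert fast == pytest.approx(slow, rel=1e-8)

    def test_target_zero_maps_to_time_zero(self, baseline):
        s = SubjectSpec(0.0, 0.5, SingleSwitchTrajectory(1.0))
        assert invert_closed_form(baseline, s, 0.0) == 0.0
        assert invert_numeric(baseline, s, 0.0) == 0.0


@st.composite
def random_instance(draw):
    family = draw(st.sampled_from(["exponential", "weibull", "gompertz"]))
    lam = draw(st.floats(1e-3, 1.0))
    if family == "exponential":
        b = BaselineHazard.exponential(lam)
    elif family == "weibull":
        b = BaselineHazard.weibull(lam, draw(st.floats(0.4, 2.5)))
    else:
        b = BaselineHazard.gompertz(lam, draw(st.floats(-0.3, 0.3)))
    eta = draw(st.floats(-1.5, 1.5))
    beta_t = draw(st.floats(-1.5, 1.5))
    kind = draw(st.sampled_from(["invariant", "single", "piecewise", "dose"]))
    if kind == "invariant":
        traj = TimeInvariantTrajectory(draw(st.floats(-1.0, 2.0)))
    elif kind == "single":
        traj = SingleSwitchTrajectory(draw(st.floats(0.0, 20.0)))
    elif kind == "piecewise":
        times = sorted(draw(st.lists(st.floats(0.05, 30.0), min_size=1, max_size=4, unique=True)))
        traj = PiecewiseBinaryTrajectory(tuple(times))
    else:
        if family == "weibull":  # no closed form there; covered by its own test
            traj = TimeInvariantTrajectory(1.0)
        else:
            traj = LinearDoseTrajectory(draw(st.floats(0.01, 1.0)))
    u = draw(st.floats(1e-6, 1.0 - 1e-6))
    return b, SubjectSpec(eta, beta_t, traj), -math.log(u)


@given(random_instance())
@settings(max_examples=250)
def test_closed_form_agrees_with_numeric_oracle(instance):
    b, s, target = instance
    t_closed = invert_closed_form(b, s, target)
    t_num = invert_numeric(b, s, target)
    if math.isinf(t_closed):
        assert math.isinf(t_num)
    else:
        assert t_closed == pytest.approx(t_num, rel=1e-8, abs=1e-10)


@given(random_instance())
@settings(max_examples=100)
def test_event_time_decreasing_in_u(instance):
    """Larger u means a smaller -log u target, hence an earlier event time."""
    b, s, target = instance
    t1 = invert_closed_form(b, s, target)
    t2 = invert_closed_form(b, s, target * 0.5)
    if not math.isinf(t1):
        assert t2 < t1 or (t2 == t1 == 0.0)


class TestPowerScaleDose:
    """The log-form dose inverse corresponds to z(t) = k*t^nu, not z(t) = k*t."""

    def test_round_trip(self):
        b = BaselineHazard.weibull(0.02, 0.7)
        s = SubjectSpec(0.4, 0.6, LinearDoseTrajectory(0.3))
        for target in (0.05, 0.8, 3.0):
            t = invert_linear_dose_weibull_powerscale(b, s, target)
            assert cumulative_hazard_powerscale_dose(
                b, s.eta, s.beta_t, 0.3, t
            ) == pytest.approx(target, rel=1e-10)

    def test_identifies_its_dose_path_by_quadrature(self):
        """H_powerscale equals the integral of h0(s)exp(eta + beta_t*k*s^nu)."""
        b = BaselineHazard.weibull(0.02, 0.7)
        eta, beta_t, k = 0.4, 0.6, 0.3

        def integrand(v):
            return b.hazard(v) * math.exp(eta + beta_t * k * v**b.nu) if v > 0 else 0.0

        for t in (0.5, 2.0, 8.0):
            val = integrate.quad(integrand, 0, t, limit=200)[0]
            assert cumulative_hazard_powerscale_dose(b, eta, beta_t, k, t) == pytest.approx(
                val, rel=1e-8
            )

    def test_differs_from_calendar_time_dose(self):
        b = BaselineHazard.weibull(0.02, 0.7)
        s = SubjectSpec(0.4, 0.6, LinearDoseTrajectory(0.3))
        t_power = invert_linear_dose_weibull_powerscale(b, s, 1.0)
        t_linear = invert_numeric(b, s, 1.0)
        assert abs(t_power - t_linear) / t_linear > 1e-3


class TestDrawEventTimes:
    def test_identical_seed_identical_output(self):
        b = BaselineHazard.weibull(0.001, 0.6)
        subs = [SubjectSpec(0.1, -0.5, SingleSwitchTrajectory(float(k))) for k in range(10)]
        a = draw_event_times(b, subs, 123)
        c = draw_event_times(b, subs, 123)
        np.testing.assert_array_equal(a, c)

    def test_null_effect_matches_untreated_path(self):
        """With beta_t = 0 the trajectory is irrelevant: same u gives the same time."""
        b = BaselineHazard.gompertz(0.2, 0.05)
        switch = [SubjectSpec(0.3, 0.0, SingleSwitchTrajectory(2.0))] * 50
        invariant = [SubjectSpec(0.3, 0.0, TimeInvariantTrajectory(0.0))] * 50
        np.testing.assert_allclose(
            draw_event_times(b, switch, 7), draw_event_times(b, invariant, 7), rtol=1e-14
        )

    def test_probability_integral_transform_small(self):
        from scipy import stats

        b = BaselineHazard.weibull(0.001, 0.6)
        subs = [SubjectSpec(0.2, -0.7, SingleSwitchTrajectory(3000.0))] * 4000
        times = draw_event_times(b, subs, 99)
        u_back = np.exp(-np.array([cumulative_hazard_tvc(b, s, t) for s, t in zip(subs, times)]))
        assert stats.kstest(u_back, "uniform").pvalue > 0.01

    def test_numeric_method_agrees(self):
        b = BaselineHazard.exponential(0.4)
        subs = [SubjectSpec(0.0, 0.7, PiecewiseBinaryTrajectory((1.0, 2.0)))] * 20
        np.testing.assert_allclose(
            draw_event_times(b, subs, 5, method="closed"),
            draw_event_times(b, subs, 5, method="numeric"),
            rtol=1e-9,
        )

    def test_empty_subjects_rejected(self):
        with pytest.raises(ValueError):
            draw_event_times(BaselineHazard.exponential(1.0), [], 0)


class TestReductionIdentities:
    """Degenerate time-varying setups reduce to the classical time-invariant draws."""

    def test_switch_at_zero_is_always_treated(self, baseline):
        s = SubjectSpec(0.4, -0.6, SingleSwitchTrajectory(0.0))
        for u in (0.05, 0.3, 0.9):
            t_tv = invert_closed_form(baseline, s, -math.log(u))
            t_ti = simulate_invariant_time(baseline, s.eta + s.beta_t, u)
            assert t_tv == t_ti or t_tv == pytest.approx(t_ti, rel=1e-14)

    def test_null_coefficient_ignores_switching(self, baseline):
        s = SubjectSpec(-0.2, 0.0, SingleSwitchTrajectory(0.8))
        for u in (0.05, 0.3, 0.9):
            t_tv = invert_closed_form(baseline, s, -math.log(u))
            t_ti = simulate_invariant_time(baseline, s.eta, u)
            assert t_tv == pytest.approx(t_ti, rel=1e-12)
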