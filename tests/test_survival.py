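"""Weibull fitting, extrapolation and transition-probability schedules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oligocea as o
from oligocea.survival import ProbSchedule, SurvivalCurve, WeibullFit

from conftest import flat_schedule


def weibull_curve(shape, scale, times, endpoint="OS", arm="a", at_risk=None):
    s = np.exp(-((np.asarray(times, float) / scale) ** shape))
    return SurvivalCurve(endpoint, arm, np.asarray(times, float), s, at_risk)


class TestFitWeibull:
    def test_noiseless_curve_recovered_exactly(self):
        curve = weibull_curve(1.3, 30.0, np.arange(3, 63, 3))
        fit = o.fit_weibull(curve)
        assert fit.shape == pytest.approx(1.3, rel=1e-6)
        assert fit.scale == pytest.approx(30.0, rel=1e-6)
        assert np.allclose(fit.log_param_cov, 0.0, atol=1e-12)

    def test_exponential_is_shape_one(self):
        t = np.arange(2, 40, 2)
        curve = SurvivalCurve("OS", "a", t, np.exp(-t / 20.0))
        fit = o.fit_weibull(curve)
        assert fit.shape == pytest.approx(1.0, rel=1e-6)
        assert fit.scale == pytest.approx(20.0, rel=1e-6)

    def test_boundary_survival_points_dropped(self):
        t = np.array([0.0, 3, 6, 9, 12, 15.0])
        s = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.0])
        fit = o.fit_weibull(SurvivalCurve("OS", "a", t, s))
        assert fit.shape > 0

    def test_too_few_points_rejected(self):
        curve = SurvivalCurve("OS", "a", [1.0, 2.0], [0.9, 0.8])
        with pytest.raises(ValueError, match="at least 3"):
            o.fit_weibull(curve)

    def test_mle_cross_check_on_synthetic_data(self):
        # independent route: lifelines' Weibull MLE on the individual
        # event times should agree with the curve-regression fit
        from lifelines import WeibullFitter

        spec = o.TrialSpec(n_per_arm=(2000, 2000), censor_rate=0.0,
                           max_followup=np.inf, seed=5)
        df = o.simulate_trial(spec)
        sub = df[df.arm == "SoC"]
        wf = WeibullFitter().fit(sub.os_time, sub.os_event)
        curve = o.km_curve(sub.os_time, sub.os_event, "OS", "SoC")
        fit = o.fit_weibull(curve)
        assert fit.shape == pytest.approx(wf.rho_, rel=0.05)
        assert fit.scale == pytest.approx(wf.lambda_, rel=0.05)

    def test_recovery_bias_shrinks_with_sample_size(self):
        shape, scale = 1.3, 30.0
        true_median = scale * np.log(2) ** (1 / shape)
        rng = np.random.default_rng(11)
        errors = {}
        for n in (100, 500, 2000):
            meds = []
            for _ in range(30):
                t = scale * rng.weibull(shape, size=n)
                curve = o.km_curve(t, np.ones(n, int))
                fit = o.fit_weibull(curve)
                meds.append(fit.scale * np.log(2) ** (1 / fit.shape))
            errors[n] = abs(np.mean(meds) - true_median) / true_median
        assert errors[2000] < 0.02
        assert errors[2000] <= errors[100] + 0.01


class TestSurvivalAt:
    def test_closed_forms(self):
        assert o.survival_at(WeibullFit(1.0, 10.0), 10.0) == pytest.approx(np.exp(-1))
        assert o.survival_at(WeibullFit(2.0, 10.0), 10.0) == pytest.approx(np.exp(-1))
        assert o.survival_at(WeibullFit(1.7, 42.0), 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            o.survival_at(WeibullFit(1.0, 10.0), -1.0)

    @settings(deadline=None, derandomize=True)
    @given(shape=st.floats(0.2, 5.0), scale=st.floats(0.5, 200.0))
    def test_monotone_decreasing(self, shape, scale):
        fit = WeibullFit(shape, scale)
        t = np.linspace(0, 10 * scale, 200)
        s = o.survival_at(fit, t)
        assert np.all(np.diff(s) <= 1e-15)
        assert s[0] == 1.0


class TestCycleTransitionProb:
    def test_exponential_closed_form_every_cycle(self):
        fit = WeibullFit(1.0, 10.0)
        expected = 1.0 - np.exp(-0.3)
        for start in np.arange(0, 120, 3.0):
            p = o.cycle_transition_prob(fit, start, 3.0)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_increasing_hazard_gives_increasing_probability(self):
        fit = WeibullFit(1.8, 30.0)
        probs = [o.cycle_transition_prob(fit, s, 3.0) for s in np.arange(0, 60, 3.0)]
        assert np.all(np.diff(probs) > 0)

    def test_vanishing_cycle_length(self):
        fit = WeibullFit(1.4, 25.0)
        assert o.cycle_transition_prob(fit, 12.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_exhausted_survival_gives_one(self):
        fit = WeibullFit(4.0, 1.0)
        assert o.cycle_transition_prob(fit, 800.0, 3.0) == 1.0


class TestBuildSchedule:
    def test_five_year_horizon_has_20_cycles(self):
        sched = o.build_schedule(WeibullFit(1.3, 30.0), 5.0, 3.0, 36.0)
        assert sched.n_cycles == 20
        regions = sched.regions()
        assert list(regions[:12]) == ["observed"] * 12
        assert list(regions[12:]) == ["projected"] * 8

    def test_zero_covariance_gives_zero_sd(self):
        sched = o.build_schedule(WeibullFit(1.3, 30.0), 5.0, 3.0, 60.0)
        assert np.all(sched.sds == 0.0)

    def test_sd_nondecreasing_across_projection_boundary(self):
        cov = np.array([[0.01, 0.002], [0.002, 0.02]])
        fit = WeibullFit(1.3, 30.0, log_param_cov=cov, resid_var=0.05)
        sched = o.build_schedule(fit, 5.0, 3.0, 36.0)
        boundary = 11  # last cycle ending within 36 months
        assert np.all(sched.sds[boundary + 1:] >= sched.sds[boundary] - 1e-15)
        assert np.all(sched.sds >= 0)

    def test_delta_method_matches_brute_force_variance(self):
        # oracle: sample (log shape, log scale) jointly and propagate
        cov = np.array([[0.004, 0.0], [0.0, 0.006]])
        fit = WeibullFit(1.3, 30.0, log_param_cov=cov)
        sched = o.build_schedule(fit, 5.0, 3.0, 60.0)
        rng = np.random.default_rng(3)
        draws = rng.multivariate_normal(
            [np.log(1.3), np.log(30.0)], cov, size=40_000)
        k = 4
        probs = [o.cycle_transition_prob(WeibullFit(np.exp(a), np.exp(b)), k * 3.0, 3.0)
                 for a, b in draws]
        assert sched.sds[k] == pytest.approx(np.std(probs), rel=0.05)


class TestEqualizeAfter:
    def make_pair(self):
        a = flat_schedule(0.05, 40, sd=0.01, arm="i")
        b = flat_schedule(0.10, 40, sd=0.02, arm="c")
        return a, b

    def test_cutoff_at_five_years_on_ten_year_grid(self):
        a, b = self.make_pair()
        out = o.equalize_after(a, b, 60.0)
        assert np.all(out.means[:20] == a.means[:20])
        assert np.all(out.means[20:] == b.means[20:])
        assert np.all(out.sds[20:] == b.sds[20:])

    def test_degenerate_cutoffs(self):
        a, b = self.make_pair()
        assert np.all(o.equalize_after(a, b, 0.0).means == b.means)
        assert np.all(o.equalize_after(a, b, 120.0).means == a.means)

    def test_mismatched_grids_rejected(self):
        a = flat_schedule(0.05, 40)
        b = flat_schedule(0.10, 20)
        with pytest.raises(ValueError, match="share"):
            o.equalize_after(a, b, 60.0)
        with pytest.raises(ValueError, match="boundary"):
            o.equalize_after(a, flat_schedule(0.1, 40), 1.7)


class TestCurveIO:
    def test_csv_round_trip(self, tmp_path):
        curve = weibull_curve(1.2, 20.0, [3, 6, 9, 12], at_risk=np.array([50, 40, 30, 20.0]))
        path = tmp_path / "c.csv"
        curve.to_csv(path)
        back = SurvivalCurve.from_csv(path, "OS", "a")
        assert np.allclose(back.times, curve.times)
        assert np.allclose(back.survival, curve.survival)
        assert np.allclose(back.at_risk, curve.at_risk)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SurvivalCurve("OS", "a", [1.0, 1.0], [0.9, 0.8])
        with pytest.raises(ValueError, match="non-increasing"):
            SurvivalCurve("OS", "a", [1.0, 2.0], [0.8, 0.9])
        with pytest.raises(ValueError, match="endpoint"):
            SurvivalCurve("TTP", "a", [1.0], [0.9])
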