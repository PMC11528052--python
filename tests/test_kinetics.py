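"""Enhancement-model evaluation, fitting, and clearance-parameter extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pactrack import kinetics as K


class TestRelativeEnhancement:
    @pytest.mark.parametrize(
        "baseline,value,expected",
        [(100.0, 100.0, 0.0), (100.0, 150.0, 50.0), (200.0, 150.0, -25.0)],
    )
    def test_formula(self, baseline, value, expected):
        raw = K.ROITimeCourse(
            times=[0.0, 1.0], values=[value, value],
            baseline_value=baseline, kind="raw-intensity",
        )
        out = K.relative_enhancement(raw)
        assert out.kind == "relative-enhancement"
        np.testing.assert_allclose(out.values, expected)
        np.testing.assert_array_equal(out.times, raw.times)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(K.InvalidBaselineError):
            K.ROITimeCourse(
                times=[0.0, 1.0], values=[1.0, 2.0],
                baseline_value=-1.0, kind="raw-intensity",
            )
        raw = K.ROITimeCourse(times=[0.0, 1.0], values=[1.0, 2.0])
        with pytest.raises(K.InvalidBaselineError):
            K.relative_enhancement(raw)

    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            K.ROITimeCourse(
                times=[0.0, 0.0], values=[1.0, 1.0],
                baseline_value=1.0, kind="raw-intensity",
            )


class TestBreathingFilter:
    def _series(self, values):
        t = np.arange(len(values), dtype=float)
        return K.ROITimeCourse(times=t, values=values, kind="relative-enhancement")

    def test_constant_series_unchanged(self):
        re = self._series(np.full(20, 5.0))
        out = K.filter_breathing_outliers(re, window=5)
        np.testing.assert_array_equal(out.values, re.values)

    def test_spike_replaced_by_local_median(self):
        vals = np.full(10, 2.0)
        vals[4] = 200.0
        out = K.filter_breathing_outliers(self._series(vals), window=5)
        assert out.values[4] == 2.0
        np.testing.assert_array_equal(np.delete(out.values, 4), np.full(9, 2.0))

    def test_smooth_curve_untouched(self, truth_params, clean_curve):
        out = K.filter_breathing_outliers(clean_curve, window=11)
        peak = clean_curve.values.max()
        assert np.max(np.abs(out.values - clean_curve.values)) < 1e-9 * peak

    def test_short_series_rejected(self):
        with pytest.raises(K.InsufficientDataError):
            K.filter_breathing_outliers(self._series(np.ones(5)), window=5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            K.filter_breathing_outliers(self._series(np.ones(20)), window=4)


class TestEMMEvaluate:
    def test_zero_before_rise_and_continuous_at_t0(self, truth_params):
        t = np.array([0.0, 4.999, 5.0, 5.0 + 1e-9])
        y = K.emm_evaluate(truth_params, t)
        assert y[0] == 0.0 and y[1] == 0.0
        assert y[2] == 0.0  # rise term vanishes exactly at t0
        assert y[3] < 1e-6

    def test_closed_form_value(self):
        p = K.EMMParams(a=100, t0=10, alpha=0.2, beta=0.01, q=1, f_ratio=1)
        val = K.emm_evaluate(p, [20.0])[0]
        expected = 100 * (1 - math.exp(-2)) * math.exp(-0.1)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(78.238, abs=5e-4)

    def test_beta_zero_monotone_with_supremum_a(self):
        p = K.EMMParams(a=50, t0=0, alpha=0.1, beta=0.0, q=1, f_ratio=1)
        t = np.linspace(0, 500, 2000)
        y = K.emm_evaluate(p, t)
        assert np.all(np.diff(y) >= 0)
        assert 49.9 < y[-1] <= 50.0

    def test_fluence_ratio_scales_pointwise(self, truth_params):
        t = np.linspace(0, 600, 200)
        y1 = K.emm_evaluate(truth_params, t)
        p2 = K.EMMParams(a=truth_params.a, t0=truth_params.t0,
                         alpha=truth_params.alpha, beta=truth_params.beta,
                         q=truth_params.q, f_ratio=2.0)
        np.testing.assert_allclose(K.emm_evaluate(p2, t), y1 / 2.0, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(1.0, 200.0),
        t0=st.floats(0.0, 50.0),
        alpha=st.floats(1e-3, 1.0),
        beta=st.floats(0.0, 0.1),
        q=st.floats(0.2, 5.0),
        f_ratio=st.floats(0.2, 5.0),
    )
    def test_bounded_by_amplitude(self, a, t0, alpha, beta, q, f_ratio):
        p = K.EMMParams(a=a, t0=t0, alpha=alpha, beta=beta, q=q, f_ratio=f_ratio)
        t = np.linspace(0, t0 + 10 / alpha, 500)
        y = K.emm_evaluate(p, t)
        assert np.all(y >= 0)
        assert np.all(y <= a / f_ratio * (1 + 1e-12))
        assert np.all(y[t < t0] == 0)


class TestFitEMM:
    def test_noise_free_recovery(self, truth_params, clean_curve):
        fit = K.fit_emm(clean_curve, f_ratio=1.0, seed=0)
        assert fit.converged
        p = fit.params
        for name in ("a", "t0", "alpha", "beta", "q"):
            assert getattr(p, name) == pytest.approx(
                getattr(truth_params, name), rel=1e-3
            )
        assert fit.residual_sum_of_squares < 1e-12

    def test_noisy_recovery_within_ten_percent(self, truth_params, clean_curve):
        rng = np.random.default_rng(42)
        noisy = K.ROITimeCourse(
            times=clean_curve.times,
            values=clean_curve.values + rng.normal(0, 2.0, clean_curve.values.size),
            kind="relative-enhancement",
        )
        fit = K.fit_emm(noisy, seed=1)
        assert fit.params.alpha == pytest.approx(truth_params.alpha, rel=0.10)
        assert fit.params.beta == pytest.approx(truth_params.beta, rel=0.10)

    def test_fluence_scaling_symmetry(self, truth_params, clean_curve):
        """A curve halved with f_ratio=2 yields the same fitted parameters."""
        halved = K.ROITimeCourse(
            times=clean_curve.times, values=clean_curve.values / 2.0,
            kind="relative-enhancement",
        )
        f1 = K.fit_emm(clean_curve, f_ratio=1.0, seed=0)
        f2 = K.fit_emm(halved, f_ratio=2.0, seed=0)
        for name in ("a", "t0", "alpha", "beta", "q"):
            assert getattr(f2.params, name) == pytest.approx(
                getattr(f1.params, name), rel=1e-4
            )

    def test_all_zero_series_rejected(self):
        t = np.arange(20.0)
        with pytest.raises(K.DegenerateInputError):
            K.fit_emm(
                K.ROITimeCourse(times=t, values=np.zeros(20),
                                kind="relative-enhancement")
            )

    def test_too_few_samples_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(K.InsufficientDataError):
            K.fit_emm(
                K.ROITimeCourse(times=t, values=np.ones(5),
                                kind="relative-enhancement")
            )


class TestClearanceSummary:
    def test_t_max_closed_form_example(self):
        p = K.EMMParams(a=100, t0=10, alpha=0.2, beta=0.01, q=1, f_ratio=1)
        expected = 10 + 5 * math.log(21)
        assert K.t_max_closed_form(p) == pytest.approx(expected, rel=1e-12)
        assert K.t_max_closed_form(p) == pytest.approx(25.223, abs=1e-3)

    def test_t_max_matches_grid_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = K.EMMParams(
                a=float(rng.uniform(10, 200)), t0=float(rng.uniform(0, 30)),
                alpha=float(rng.uniform(0.01, 0.5)),
                beta=float(rng.uniform(1e-4, 0.05)),
                q=float(rng.uniform(0.3, 4.0)),
            )
            tm = K.t_max_closed_form(p)
            grid = np.arange(p.t0, tm + 50.0, 1e-3)
            brute = grid[np.argmax(K.emm_evaluate(p, grid))]
            assert abs(tm - brute) <= 1e-3 + 1e-9

    def test_summary_values(self, truth_params, clean_curve):
        fit = K.fit_emm(clean_curve, seed=0)
        s = K.clearance_summary(fit, t_end=600.0)
        p = fit.params
        assert s.t_max >= p.t0
        assert s.re_max_curve <= s.re_max_amplitude
        assert s.u_alpha == pytest.approx(60 * p.alpha)
        assert s.e_beta == pytest.approx(60 * p.beta)
        # half-life definition: curve at t_max + t_half is half the peak
        half_val = K.emm_evaluate(p, [s.t_max + s.t_half])[0]
        assert half_val == pytest.approx(0.5 * s.re_max_curve, rel=1e-6)
        assert s.auc >= 0

    def test_beta_zero_half_life_sentinel(self):
        p = K.EMMParams(a=50, t0=1.0, alpha=0.1, beta=0.0, q=1.0)
        fit = K.EMMFit(params=p, residual_sum_of_squares=0.0, n_points=100,
                       converged=True)
        s = K.clearance_summary(fit, t_end=100.0)
        assert math.isinf(s.t_half)
        assert s.t_max == 100.0  # clamped to window end

    def test_auc_monotone_in_window(self, clean_curve):
        fit = K.fit_emm(clean_curve, seed=0)
        aucs = [K.clearance_summary(fit, t_end=te).auc for te in (100, 300, 600)]
        assert aucs[0] <= aucs[1] <= aucs[2]

    def test_raw_auc_of_constant_curve(self):
        t = np.linspace(0, 100, 51)
        raw = K.ROITimeCourse(times=t, values=np.full(51, 7.0),
                              kind="relative-enhancement")
        p = K.EMMParams(a=7, t0=0.01, alpha=1.0, beta=0.001, q=1.0)
        fit = K.EMMFit(params=p, residual_sum_of_squares=0.0, n_points=51,
                       converged=True)
        s = K.clearance_summary(fit, t_end=100.0, raw=raw, auc_mode="raw")
        assert s.auc == pytest.approx(7.0 * 100.0)


def test_csv_round_trip(tmp_path, clean_curve):
    path = tmp_path / "curve.csv"
    clean_curve.to_csv(path)
    back = K.ROITimeCourse.from_csv(path)
    np.testing.assert_allclose(back.times, clean_curve.times)
    np.testing.assert_allclose(back.values, clean_curve.values)
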