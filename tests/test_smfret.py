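"""Histogram building, double-Gaussian fitting, correlation analysis, decay
fitting, and two-state rate estimation."""

import math

import numpy as np
import pytest
from scipy import stats

from allofret.smfret import (CorrelationCurve, IntensityTrace,
                             NormalizedHistogram, TwoStateEstimator,
                             autocorrelation, build_histogram, compute_fret,
                             correlation_single, estimate_two_state,
                             fit_decays, fit_double_gaussian, linear_fit)
from allofret.telegraph import simulate_ensemble

from conftest import nested_loop_correlation


class TestComputeFret:
    @pytest.mark.parametrize("ia,id_,expected", [
        (30.0, 70.0, 0.30),
        (50.0, 50.0, 0.50),
    ])
    def test_arithmetic(self, ia, id_, expected):
        trace = IntensityTrace(I_D=np.full(4, id_), I_A=np.full(4, ia), dt=0.1)
        np.testing.assert_allclose(compute_fret(trace).values, expected)

    def test_anticorrelated_ramp(self):
        ia = np.linspace(0, 100, 11)
        trace = IntensityTrace(I_D=100 - ia, I_A=ia, dt=0.1)
        np.testing.assert_allclose(compute_fret(trace).values,
                                   np.linspace(0, 1, 11))

    def test_zero_total_frame_names_index(self):
        trace = IntensityTrace(I_D=np.array([50.0, 0.0]),
                               I_A=np.array([50.0, 0.0]), dt=0.1)
        with pytest.raises(ValueError, match="frame 1"):
            compute_fret(trace)


class TestHistogram:
    def test_auto_bin_width_floor(self):
        rng = np.random.default_rng(0)
        h = build_histogram(rng.uniform(0, 1, 40_000))
        assert h.bin_width >= 0.005  # 1/sqrt(40,000) = 0.005

    def test_auto_bin_width_scales_with_n(self):
        rng = np.random.default_rng(0)
        h = build_histogram(rng.uniform(0, 1, 1000))
        assert h.bin_width == pytest.approx(1 / math.sqrt(1000))

    def test_uniform_density_flat(self):
        # chi-square against flatness must not reject at 0.01
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, 1000)
        h = build_histogram(vals)
        expected = h.counts.sum() / h.counts.size
        chi2 = np.sum((h.counts - expected) ** 2 / expected)
        p = stats.chi2.sf(chi2, df=h.counts.size - 1)
        assert p > 0.01
        np.testing.assert_allclose(h.density.mean(), 1.0, rtol=0.05)

    def test_sqrt_count_errors(self):
        # a bin holding 16 raw counts carries error 4/area
        vals = np.concatenate([np.full(16, 0.25), np.full(84, 0.75)])
        h = build_histogram(vals, bin_width=0.5)
        area = h.counts.sum() * h.bin_width
        idx = int(np.flatnonzero(h.counts == 16)[0])
        assert h.density_err[idx] == pytest.approx(4 / area)

    @pytest.mark.parametrize("seed,n", [(0, 100), (1, 5000), (2, 123_456)])
    def test_area_is_one(self, seed, n):
        rng = np.random.default_rng(seed)
        h = build_histogram(rng.normal(0.5, 0.1, n))
        assert h.area == pytest.approx(1.0, abs=1e-9)

    def test_identical_values_single_bin(self):
        h = build_histogram(np.full(10, 0.4))
        assert h.counts.size == 1
        assert h.warning is not None


class TestDoubleGaussian:
    TRUE = (3.0, 0.44, 0.04, 5.0, 0.55, 0.03)

    def _exact_hist(self):
        x = np.arange(0.3, 0.71, 0.005)
        a1, b1, c1, a2, b2, c2 = self.TRUE
        y = (a1 * np.exp(-((x - b1) / c1) ** 2)
             + a2 * np.exp(-((x - b2) / c2) ** 2))
        edges = np.append(x - 0.0025, x[-1] + 0.0025)
        return NormalizedHistogram(bin_edges=edges, density=y,
                                   density_err=np.zeros_like(y),
                                   n_values=10_000, counts=np.zeros_like(y))

    def test_exact_curve_recovery(self):
        f = fit_double_gaussian(self._exact_hist())
        got = (f.a1, f.b1, f.c1, f.a2, f.b2, f.c2)
        np.testing.assert_allclose(got, self.TRUE, rtol=1e-6)
        # analytic areas
        assert f.area1 == pytest.approx(3.0 * 0.04 * math.sqrt(math.pi))

    def test_single_gaussian_data_degenerates_cleanly(self):
        rng = np.random.default_rng(4)
        h = build_histogram(rng.normal(0.5, 0.03, 40_000))
        f = fit_double_gaussian(h)
        ratio = f.area_ratio
        assert ratio >= 50 or ratio <= 1 / 50
        dominant_center = f.b1 if ratio <= 1 else f.b2
        assert abs(dominant_center - 0.5) < h.bin_width
        assert f.degenerate

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0.44, 0.03, 30_000),
                               rng.normal(0.55, 0.03, 20_000)])
        f = fit_double_gaussian(build_histogram(vals))
        g = fit_double_gaussian(build_histogram(1.0 - vals))
        assert g.b1 == pytest.approx(1 - f.b2, abs=2e-3)
        assert g.b2 == pytest.approx(1 - f.b1, abs=2e-3)

    def test_too_few_bins_raises(self):
        h = build_histogram(np.array([0.1, 0.1, 0.9, 0.9]), bin_width=0.5)
        with pytest.raises(ValueError, match="populated bins"):
            fit_double_gaussian(h)


class TestAutocorrelation:
    def test_constant_series_is_zero_and_flagged(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            curve = autocorrelation([np.full(100, 0.5)], max_lag=10)
        np.testing.assert_array_equal(curve.C, 0.0)
        assert curve.flat and not curve.normalized

    def test_alternating_series_matches_nested_loop(self):
        x = np.array([1.0, -1.0] * 4)
        got = correlation_single(x, 3)
        for tau in range(4):
            assert got[tau] == pytest.approx(
                nested_loop_correlation(x, tau), rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorized_equals_nested_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=257)
        got = correlation_single(x, 20)
        want = [nested_loop_correlation(x, tau) for tau in range(21)]
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(7)
        n = 20_000
        curve = autocorrelation([rng.normal(size=n)], max_lag=50)
        assert np.all(np.abs(curve.C[1:]) < 4 / math.sqrt(n))

    def test_sem_over_trajectories(self, noisy_ensemble):
        curve = autocorrelation(noisy_ensemble[:5], max_lag=20)
        assert curve.sem.shape == curve.C.shape
        assert np.all(curve.sem[1:] > 0)


class TestDecayFits:
    @staticmethod
    def _curve(values):
        lags = np.arange(values.size)
        return CorrelationCurve(lags=lags, C=values,
                                sem=np.zeros_like(values), normalized=True,
                                n_trajectories=1)

    def test_exact_exponential_recovery(self):
        tau = np.arange(1001, dtype=float)
        fits = fit_decays(self._curve(np.exp(-0.008 * tau)), (1, 1000))
        assert fits.exp_e == pytest.approx(0.008, abs=1e-4)
        assert fits.exp_d == pytest.approx(1.0, abs=1e-3)
        assert abs(fits.exp_f) < 1e-3

    def test_exact_power_law_recovery(self):
        tau = np.arange(1001, dtype=float)
        fits = fit_decays(self._curve((0.01 * tau + 1) ** -1.3), (1, 1000))
        assert fits.power_a == pytest.approx(0.01, abs=1e-3)
        assert fits.power_b == pytest.approx(1.3, abs=1e-3)

    def test_power_law_boundary_condition(self):
        tau = np.arange(1001, dtype=float)
        fits = fit_decays(self._curve((0.02 * tau + 1) ** -0.7), (1, 1000))
        assert fits.power_law(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_lag_range_validation(self):
        tau = np.arange(101, dtype=float)
        with pytest.raises(ValueError, match="exceeds"):
            fit_decays(self._curve(np.exp(-0.01 * tau)), (1, 1000))


class TestTwoStateEstimate:
    @staticmethod
    def _fit(ratio):
        from allofret.smfret import DoubleGaussianFit
        return DoubleGaussianFit(a1=1.0, b1=0.46, c1=0.04, a2=ratio,
                                 b2=0.52, c2=0.04, residual_norm=0.0,
                                 n_starts=1)

    @staticmethod
    def _decays(e):
        from allofret.smfret import DecayFits
        return DecayFits(power_a=1, power_b=1, exp_d=1, exp_e=e, exp_f=0,
                         ss_power=1, ss_exp=0.5, lag_range=(1, 1000))

    @pytest.mark.parametrize("ratio,rate_sum,k1,k2", [
        (1.0, 0.08, 0.04, 0.04),
        (3.0, 0.08, 0.06, 0.02),
    ])
    def test_rate_arithmetic(self, ratio, rate_sum, k1, k2):
        est = estimate_two_state(self._fit(ratio), self._decays(rate_sum * 0.1),
                                 dt=0.1)
        assert est.rate_ratio == pytest.approx(ratio)
        assert est.rate_sum == pytest.approx(rate_sum)
        assert est.k1 == pytest.approx(k1)
        assert est.k2 == pytest.approx(k2)
        # internal consistency k1 = rate_sum * ratio/(1+ratio)
        assert est.k1 == pytest.approx(est.rate_sum * est.rate_ratio
                                       / (1 + est.rate_ratio))

    def test_round_trip_recovers_rates(self, noisy_ensemble, asyn_params):
        est = TwoStateEstimator(fit_max_lag=1000).fit(noisy_ensemble)
        assert est.k1_ == pytest.approx(asyn_params.k1, rel=0.25)
        assert est.k2_ == pytest.approx(asyn_params.k2, rel=0.25)

    def test_noise_widens_gaussians(self, asyn_params):
        # paired ensembles at two noise levels, common seeds
        from allofret.telegraph import TwoStateParams
        narrow = TwoStateParams(asyn_params.S1, asyn_params.S2, 0.04, 0.04,
                                sigma1=0.02, sigma2=0.02)
        wide = TwoStateParams(asyn_params.S1, asyn_params.S2, 0.04, 0.04,
                              sigma1=0.04, sigma2=0.04)
        e1 = TwoStateEstimator().fit(simulate_ensemble(narrow, 20, 2000, 0.1,
                                                       seed=33))
        e2 = TwoStateEstimator().fit(simulate_ensemble(wide, 20, 2000, 0.1,
                                                       seed=33))
        assert e2.gaussian_fit_.c1 > e1.gaussian_fit_.c1
        assert e2.gaussian_fit_.c2 > e1.gaussian_fit_.c2

    def test_sklearn_protocol(self):
        est = TwoStateEstimator(dt=0.2)
        assert est.get_params()["dt"] == 0.2
        est.set_params(max_lag=50)
        assert est.max_lag == 50


class TestLinearFit:
    def test_exact_line_zero_width_band(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linear_fit(x, 2 + 3 * x)
        assert fit.b0 == pytest.approx(2.0, abs=1e-10)
        assert fit.b1 == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(fit.ci_upper - fit.ci_lower, 0.0,
                                   atol=1e-8)

    def test_hand_computed_normal_equations(self):
        fit = linear_fit(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 3.0]))
        assert fit.b1 == pytest.approx(1.5)
        assert fit.b0 == pytest.approx(-0.5)

    def test_band_narrowest_at_mean_x(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 25)
        y = 1 + 0.5 * x + rng.normal(0, 0.3, x.size)
        fit = linear_fit(x, y)
        widths = fit.ci_upper - fit.ci_lower
        assert np.argmin(widths) == np.argmin(np.abs(x - x.mean()))

    def test_constant_x_raises(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit(np.ones(5), np.arange(5.0))
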