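"""FIR design, AR(1) estimation, GLS fitting and the partial F-test."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import lfilter

import nirsdot as nd
from nirsdot.glm import _BatchDeconvolver, build_design_matrix
from nirsdot.simulate import Paradigm


def _ar1_series(rng, rho, n, sigma=1.0):
    e = rng.normal(0, sigma, n)
    e[0] /= np.sqrt(1 - rho**2)
    return lfilter([1.0], [1.0, -rho], e)


class TestDesignMatrix:
    def test_drift_count_at_standard_run(self, paradigm):
        X = build_design_matrix(paradigm, (-5.0, 30.0), 0.01)
        # frequencies (m-1)/1200 Hz < 0.01 admit m = 1..12
        assert X.M == 12
        assert X.L == X.K + 12
        assert X.K == 176  # samples from -25 to +150 inclusive

    def test_fir_columns_are_shifted_stimulus(self):
        p = Paradigm([0.6], [0.2], 2.0, 5.0)  # one event at sample 3, N=10
        X = build_design_matrix(p, (0.0, 0.4), drift_cutoff_hz=0.01)
        assert X.K == 3
        for j in range(3):
            expected = np.zeros(10)
            expected[3 + j] = 1.0
            np.testing.assert_array_equal(X.X[:, j], expected)

    def test_negative_window_advances_stimulus(self):
        p = Paradigm([0.6], [0.2], 2.0, 5.0)
        X = build_design_matrix(p, (-0.4, 0.0), drift_cutoff_hz=0.01)
        # first column is the stimulus advanced by 2 samples
        expected = np.zeros(10)
        expected[1] = 1.0
        np.testing.assert_array_equal(X.X[:, 0], expected)

    def test_drift_block_is_orthonormal(self, paradigm):
        X = build_design_matrix(paradigm)
        D = X.X[:, X.K :]
        np.testing.assert_allclose(D.T @ D, np.eye(X.M), atol=1e-10)

    def test_rebuild_is_bit_identical(self, paradigm):
        a = build_design_matrix(paradigm)
        b = build_design_matrix(paradigm)
        np.testing.assert_array_equal(a.X, b.X)

    def test_no_events_flagged_rank_deficient(self):
        p = Paradigm([], [], 100.0, 5.0)
        X = build_design_matrix(p, (0.0, 2.0))
        assert X.rank_deficient


class TestEstimateAR1:
    def test_white_noise_near_zero(self, rng):
        ar = nd.estimate_ar1(rng.normal(size=3000))
        assert abs(ar.rho) < 0.05

    def test_recovers_simulated_coefficient(self, rng):
        x = _ar1_series(rng, 0.7, 3000)
        assert nd.estimate_ar1(x).rho == pytest.approx(0.7, abs=0.05)

    def test_alternating_sequence_clipped(self):
        x = np.tile([1.0, -1.0], 50)
        assert nd.estimate_ar1(x).rho == -0.99

    def test_constant_residuals_degenerate(self):
        ar = nd.estimate_ar1(np.ones(10))
        assert ar.rho == 0.0 and ar.degenerate


class TestFitGLS:
    def test_perfect_fit_ols_case(self):
        p = Paradigm([0.6], [0.2], 4.0, 5.0)
        X = build_design_matrix(p, (0.0, 0.4), drift_cutoff_hz=0.2)
        beta = np.linspace(0.5, 1.5, X.L)
        y = X.X @ beta  # y lies exactly in the column space
        fit = nd.fit_gls(y, X, nd.ARModel(0.0))
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-10)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_at_rho_zero(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 10.0))
        y = rng.normal(size=X.N)
        fit = nd.fit_gls(y, X, nd.ARModel(0.0))
        beta_ols, *_ = np.linalg.lstsq(X.X, y, rcond=None)
        np.testing.assert_allclose(fit.beta_hat, beta_ols, atol=1e-10)

    def test_matches_dense_omega_oracle(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-1.0, 6.0))
        n = X.N
        rho = 0.7
        y = rng.normal(size=n)
        omega_inv = np.linalg.inv(
            rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        )
        beta = np.linalg.solve(X.X.T @ omega_inv @ X.X, X.X.T @ omega_inv @ y)
        fit = nd.fit_gls(y, X, nd.ARModel(rho))
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-10)
        resid = y - X.X @ beta
        np.testing.assert_allclose(
            fit.sigma2_hat, resid @ omega_inv @ resid / n, rtol=1e-10
        )
        theta = np.linalg.inv(X.X.T @ omega_inv @ X.X)[: X.K, : X.K]
        np.testing.assert_allclose(fit.theta_h, theta, atol=1e-10)


class TestTwoPassDeconvolution:
    def test_exact_recovery_on_noise_free_signal(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 10.0))
        beta = rng.normal(size=X.L)
        fit = nd.deconvolve_ar1_mle(X.X @ beta, X)
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-8)
        assert fit.sigma2_hat < 1e-16

    def test_estimates_within_gls_standard_errors(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 10.0))
        beta = np.zeros(X.L)
        beta[5] = 2.0
        bad = 0
        for _ in range(20):
            y = X.X @ beta + _ar1_series(rng, 0.5, X.N, 0.5)
            fit = nd.deconvolve_ar1_mle(y, X)
            se = np.sqrt(fit.sigma2_hat * np.diag(fit.theta_h))
            if abs(fit.beta_hat[5] - 2.0) > 3 * se[5]:
                bad += 1
        assert bad <= 2

    def test_carries_estimated_rho(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 10.0))
        y = _ar1_series(rng, 0.6, X.N)
        fit = nd.deconvolve_ar1_mle(y, X)
        assert 0.3 < fit.rho_used < 0.9


class TestPartialFTest:
    def test_zero_hrf_coefficients_give_zero_f(self, small_paradigm):
        X = build_design_matrix(small_paradigm, (0.0, 2.0))
        # pure drift signal: HRF block orthogonal complement
        y = X.X[:, X.K] * 3.0
        fit = nd.fit_gls(y, X, nd.ARModel(0.0))
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(fit.beta_hat[: X.K], 0.0, atol=1e-10)

    def test_f_equals_squared_t_for_single_coefficient(self, rng):
        p = Paradigm([2.0], [0.2], 40.0, 5.0)
        X = build_design_matrix(p, (0.0, 0.0), drift_cutoff_hz=0.011)
        assert X.K == 1
        y = rng.normal(size=X.N) + 0.5 * X.X[:, 0]
        fit = nd.fit_gls(y, X, nd.ARModel(0.0))
        se2 = fit.sigma2_hat * fit.theta_h[0, 0]
        t2 = fit.beta_hat[0] ** 2 / se2 * (X.N - X.L) / X.N
        assert fit.F_stat == pytest.approx(t2, rel=1e-10)

    def test_invariant_to_data_rescaling(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 10.0))
        y = rng.normal(size=X.N)
        f1 = nd.fit_gls(y, X, nd.ARModel(0.3)).F_stat
        f2 = nd.fit_gls(7.5 * y, X, nd.ARModel(0.3)).F_stat
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_null_distribution_matches_f(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-1.0, 6.0))
        eng = _BatchDeconvolver(X)
        Y = rng.normal(size=(X.N, 400))
        res = eng.fit(Y)
        ks = stats.kstest(res["F"], stats.f(X.K, X.N - X.L).cdf)
        assert ks.pvalue > 0.01

    def test_moderate_null_calibration(self, small_paradigm, rng):
        # white-ish AR(1) null through the full two-pass pipeline
        X = build_design_matrix(small_paradigm, (-1.0, 6.0))
        eng = _BatchDeconvolver(X)
        E = rng.normal(size=(X.N, 300))
        E[0] /= np.sqrt(1 - 0.25)
        Y = lfilter([1.0], [1.0, -0.5], E, axis=0)
        res = eng.fit(Y)
        rate = np.mean(res["p"] < 0.05)
        assert 0.015 <= rate <= 0.10


class TestBatchEngine:
    def test_matches_single_series_path(self, small_paradigm, rng):
        X = build_design_matrix(small_paradigm, (-2.0, 8.0))
        Y = rng.normal(size=(X.N, 4)) + np.outer(X.X[:, 3], [0, 1, 2, 3])
        res = _BatchDeconvolver(X).fit(Y)
        for v in range(4):
            fit = nd.deconvolve_ar1_mle(Y[:, v], X)
            np.testing.assert_allclose(res["beta"][:, v], fit.beta_hat, atol=1e-9)
            assert res["F"][v] == pytest.approx(fit.F_stat, rel=1e-9)
            assert res["rho"][v] == pytest.approx(fit.rho_used, abs=1e-12)


class TestSensorSNR:
    def test_constructed_zero_db_channel(self, surface, montage, sensitivity,
                                         paradigm):
        ds = nd.simulate_dataset(surface, montage, sensitivity, 1, paradigm,
                                 0.0, seed=6)
        y = ds.od_sim.values[830.0][ds.best_channel]
        est = nd.estimate_sensor_snr(y, paradigm)
        assert est == pytest.approx(0.0, abs=3.0)

    def test_pure_noise_strongly_negative(self, paradigm, rng):
        # the FIR block absorbs ~K/N of the noise power, bounding how
        # negative the estimate can get (~ -10 dB for K=176, N=3000)
        y = _ar1_series(rng, 0.5, paradigm.n_samples)
        assert nd.estimate_sensor_snr(y, paradigm) < -8.0

    def test_noise_free_channel_large_positive(self, surface, montage,
                                               sensitivity, paradigm):
        ds = nd.simulate_dataset(surface, montage, sensitivity, 1, paradigm,
                                 0.0, seed=6)
        y = ds.od_noise_free.values[830.0][ds.best_channel]
        assert nd.estimate_sensor_snr(y, paradigm) > 20.0
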