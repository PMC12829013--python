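"""Semivariograms, likelihood filter, model selection, derived metrics."""

import numpy as np
import pytest

from tandemtrack._kalman import whiten
from tandemtrack.ctmm_core import (
    aicc,
    average_semivariograms,
    effective_sample_size,
    empirical_semivariogram,
    fit_ctmm,
    fit_family,
    model_semivariance,
    periodicity,
    range_residency_diagnostic,
    rmspe_cv,
)
from tandemtrack.types import LocationSeries, MovementModel, Semivariogram, SECONDS_PER_DAY

DAY = SECONDS_PER_DAY


def _series(t, x, y, err=0.0):
    n = len(t)
    return LocationSeries("s", np.asarray(t, float), np.zeros(n), np.zeros(n),
                          x=np.asarray(x, float), y=np.asarray(y, float),
                          error_radius=np.full(n, err))


class TestModelSemivariance:
    def test_ou_at_one_timescale(self):
        m = MovementModel("OU", sigma2=1.0, tau_pos=10 * DAY)
        assert model_semivariance(m, 10 * DAY) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("family,kw", [
        ("IID", {}),
        ("OU", {"tau_pos": 10 * DAY}),
        ("OUF", {"tau_pos": 10 * DAY, "tau_v": 1 * DAY}),
    ])
    def test_sill_at_large_lag(self, family, kw):
        m = MovementModel(family, sigma2=3.7, **kw)
        assert model_semivariance(m, 1e12) == pytest.approx(3.7, rel=1e-9)

    def test_ouf_value_and_monotonicity(self):
        m = MovementModel("OUF", sigma2=1.0, tau_pos=10 * DAY, tau_v=1 * DAY)
        assert model_semivariance(m, 10 * DAY) == pytest.approx(0.5913, abs=5e-4)
        lags = np.linspace(0, 100 * DAY, 500)
        g = model_semivariance(m, lags)
        assert np.all(np.diff(g) >= -1e-15) and g[0] == 0.0

    def test_repeated_root_limit_continuous(self):
        near = MovementModel("OUF", sigma2=1.0, tau_pos=5 * DAY, tau_v=5 * DAY * (1 - 1e-12))
        exact = MovementModel("OUF", sigma2=1.0, tau_pos=5 * DAY, tau_v=5 * DAY)
        lag = 3 * DAY
        assert model_semivariance(near, lag) == pytest.approx(
            model_semivariance(exact, lag), rel=1e-6
        )

    def test_ouf_matches_empirical_variogram_of_simulated_paths(self):
        from tandemtrack.synthetic_data import SimulationConfig, simulate_trajectory

        cfg = SimulationConfig(seed=1, tau_pos=10 * DAY, tau_v=1 * DAY, sigma2=1.0,
                               duration=30 * DAY)
        lag_d = 10
        vals = []
        for s in range(400):
            tr = simulate_trajectory(cfg, "x", rng=np.random.default_rng(3000 + s),
                                     migratory=False)
            step = int(round(lag_d * DAY / (tr.t[1] - tr.t[0])))
            vals.append((tr.x[-1] - tr.x[-1 - step]) ** 2 + (tr.y[-1] - tr.y[-1 - step]) ** 2)
        emp = np.mean(vals) / 4.0
        m = MovementModel("OUF", sigma2=1.0, tau_pos=10 * DAY, tau_v=1 * DAY)
        assert emp == pytest.approx(model_semivariance(m, lag_d * DAY), rel=0.15)


class TestEmpiricalSemivariogram:
    def test_identical_points_zero(self):
        s = _series([0, DAY, 2 * DAY], [5, 5, 5], [7, 7, 7])
        sv = empirical_semivariogram(s)
        np.testing.assert_allclose(sv.gamma, 0.0)

    def test_two_points_quarter_squared_distance(self):
        s = _series([0, DAY], [0, 3], [0, 4])  # distance 5
        sv = empirical_semivariogram(s)
        assert sv.gamma.size == 1 and sv.gamma[0] == pytest.approx(25.0 / 4.0)
        assert sv.counts[0] == 1

    def test_white_noise_plateaus_at_variance(self):
        rng = np.random.default_rng(0)
        n = 2000
        s = _series(np.arange(n) * DAY, rng.normal(0, 3.0, n), rng.normal(0, 3.0, n))
        sv = empirical_semivariogram(s)
        assert np.mean(sv.gamma[5:]) == pytest.approx(9.0, rel=0.1)


class TestAverageSemivariograms:
    def test_self_average_identity(self):
        sv = Semivariogram(np.array([0.5, 1.5]) * DAY, np.array([1.0, 2.0]), np.array([3, 4]))
        out = average_semivariograms([sv, sv])["all"]
        np.testing.assert_allclose(out.gamma, sv.gamma)
        np.testing.assert_allclose(out.counts, 2 * sv.counts)

    def test_zero_count_bin_ignored(self):
        a = Semivariogram(np.array([0.5]) * DAY, np.array([2.0]), np.array([5]))
        b = Semivariogram(np.array([0.5, 1.5]) * DAY, np.array([4.0, 7.0]), np.array([5, 2]))
        out = average_semivariograms([a, b])["all"]
        assert out.gamma[1] == pytest.approx(7.0)

    def test_count_weighting(self):
        a = Semivariogram(np.array([0.5]) * DAY, np.array([0.0]), np.array([1]))
        b = Semivariogram(np.array([0.5]) * DAY, np.array([4.0]), np.array([3]))
        out = average_semivariograms([a, b])["all"]
        assert out.gamma[0] == pytest.approx(3.0)

    def test_mismatched_grids_rejected(self):
        a = Semivariogram(np.array([0.5]) * DAY, np.array([1.0]), np.array([1]), bin_width=DAY)
        b = Semivariogram(np.array([0.25]) * DAY, np.array([1.0]), np.array([1]), bin_width=DAY / 2)
        with pytest.raises(ValueError):
            average_semivariograms([a, b])


class TestRangeResidency:
    def test_flat_variogram_resident_score_one(self):
        sv = Semivariogram(np.arange(10) * DAY + DAY / 2, np.full(10, 2.0), np.full(10, 50))
        label, score = range_residency_diagnostic(sv)
        assert label == "resident" and score == pytest.approx(1.0)

    def test_too_few_bins_indeterminate(self):
        sv = Semivariogram(np.arange(3) * DAY, np.ones(3), np.ones(3))
        assert range_residency_diagnostic(sv)[0] == "indeterminate"

    def test_ou_simulation_resident_drift_not(self):
        from tandemtrack.synthetic_data import SimulationConfig, observe_gps, simulate_trajectory

        def label_for(tau_pos_d):
            cfg = SimulationConfig(seed=2, tau_pos=tau_pos_d * DAY,
                                   tau_v=0.3 * DAY, duration=600 * DAY)
            rng = np.random.default_rng(21)
            traj = simulate_trajectory(cfg, "x", rng=rng, migratory=False)
            obs = observe_gps(traj, cfg, rng=rng)
            return range_residency_diagnostic(empirical_semivariogram(obs))[0]

        assert label_for(10) == "resident"
        assert label_for(10_000) == "non-resident"


class TestAicc:
    def test_zero_params_is_minus_two_loglik(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_worked_value(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(206.5217, abs=1e-3)

    def test_correction_positive_and_inadmissible_models(self):
        assert aicc(-10.0, 2, 30) >= -2 * (-10.0) + 2 * 2
        assert aicc(-10.0, 5, 6) == np.inf


class TestLikelihoodFilter:
    def test_ou_filter_equals_closed_form_ar1(self):
        rng = np.random.default_rng(0)
        n, tau, sig2 = 200, 5.0, 2.0
        phi = np.exp(-1.0 / tau)
        y = np.empty(n)
        y[0] = rng.normal(0, np.sqrt(sig2))
        iv = sig2 * (1 - phi**2)
        for i in range(1, n):
            y[i] = phi * y[i - 1] + rng.normal(0, np.sqrt(iv))
        W, logdet = whiten("OU", np.ones(n - 1), np.zeros(n), y[:, None], sig2, tau, 0.0)
        ll = -0.5 * float((W**2).sum()) - 0.5 * logdet - n / 2 * np.log(2 * np.pi)
        ll_ar1 = -0.5 * np.log(2 * np.pi * sig2) - y[0] ** 2 / (2 * sig2) + np.sum(
            -0.5 * np.log(2 * np.pi * iv) - (y[1:] - phi * y[:-1]) ** 2 / (2 * iv)
        )
        assert abs(ll - ll_ar1) / abs(ll_ar1) < 1e-8

    def test_ouf_filter_matches_dense_gaussian_loglik(self):
        # small-n oracle: whitened loglik vs explicit multivariate normal
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 40, 25)) * DAY
        tp, tv, sig2 = 8 * DAY, 0.5 * DAY, 4.0
        r1, r2 = 1 / tp, 1 / tv
        lagm = np.abs(t[:, None] - t[None, :])
        C = sig2 * (r2 * np.exp(-r1 * lagm) - r1 * np.exp(-r2 * lagm)) / (r2 - r1)
        y = rng.multivariate_normal(np.zeros(25), C)
        W, logdet = whiten("OUF", np.diff(t), np.zeros(25), y[:, None], sig2, tp, tv)
        ll = -0.5 * float((W**2).sum()) - 0.5 * logdet - 25 / 2 * np.log(2 * np.pi)
        ll_ref = multivariate_normal(np.zeros(25), C).logpdf(y)
        assert abs(ll - ll_ref) / abs(ll_ref) < 1e-8


class TestFitting:
    def test_white_noise_selects_iid(self):
        rng = np.random.default_rng(4)
        n = 300
        s = _series(np.arange(n) * DAY, rng.normal(0, 100.0, n), rng.normal(0, 100.0, n))
        models = fit_ctmm(s, harmonic_grid=(0, 1))
        assert models[0].family == "IID"

    def test_model_nesting_logliks(self, resident_bird):
        _, _, series, _ = resident_bird
        ms = {f: fit_family(series, f, n_harmonics=0) for f in ("IID", "OU", "OUF")}
        assert ms["OUF"].loglik >= ms["OU"].loglik - 1e-3
        assert ms["OU"].loglik >= ms["IID"].loglik - 1e-3

    def test_ou_recovery_and_selection(self):
        from tandemtrack.synthetic_data import SimulationConfig, observe_gps, simulate_trajectory

        cfg = SimulationConfig(seed=5, tau_pos=14 * DAY, tau_v=0.3 * DAY, duration=600 * DAY)
        rng = np.random.default_rng(55)
        traj = simulate_trajectory(cfg, "x", rng=rng, migratory=False)
        obs = observe_gps(traj, cfg, rng=rng)
        models = fit_ctmm(obs, harmonic_grid=(0,))
        best = models[0]
        assert best.family in ("OU", "OUF")
        assert best.tau_pos / DAY == pytest.approx(14.0, rel=0.5)

    def test_migratory_bird_selects_harmonics(self, fitted_gps_bird):
        _, _, _, models = fitted_gps_bird
        assert models[0].n_harmonics >= 1

    def test_fitted_variogram_tracks_empirical(self, resident_bird):
        _, _, series, model = resident_bird
        sv = empirical_semivariogram(series)
        short = sv.lag <= 5 * model.tau_pos
        pred = model_semivariance(model, sv.lag[short])
        # fitted curve within a generous envelope of the empirical variogram
        resid = np.abs(pred - sv.gamma[short]) / model.sigma2
        assert np.median(resid) < 0.5


class TestDerivedMetrics:
    def test_ess_iid_counts_observations(self):
        m = MovementModel("IID", sigma2=1.0, n_obs=100, duration=99 * DAY)
        assert effective_sample_size(m) == 100

    def test_ess_range_crossings(self):
        m = MovementModel("OU", sigma2=1.0, tau_pos=14.6 * DAY, n_obs=366, duration=365 * DAY)
        assert effective_sample_size(m) == pytest.approx(25.0, rel=1e-9)

    def test_ess_below_one_when_tau_exceeds_duration(self):
        m = MovementModel("OU", sigma2=1.0, tau_pos=400 * DAY, n_obs=100, duration=300 * DAY)
        assert effective_sample_size(m) < 1.0

    def test_periodicity_zero_without_harmonics(self):
        m = MovementModel("OU", sigma2=1.0, tau_pos=DAY, n_harmonics=0)
        assert periodicity(m) == 0.0

    def test_periodicity_extremes_and_half(self):
        coeffs = np.zeros((2, 3))
        coeffs[:, 1] = np.sqrt(2.0)  # per-axis amplitude A with A^2/2 = 1
        m = MovementModel("OU", sigma2=1.0, tau_pos=DAY, n_harmonics=1, mean_coeffs=coeffs)
        assert periodicity(m) == pytest.approx(50.0)
        m_tiny = MovementModel("OU", sigma2=1e-12, tau_pos=DAY, n_harmonics=1, mean_coeffs=coeffs)
        assert periodicity(m_tiny) == pytest.approx(100.0, abs=1e-6)

    def test_periodicity_monte_carlo_variance_decomposition(self):
        # simulated migratory bird: share of variance explained by the loop
        from tandemtrack.synthetic_data import (
            SimulationConfig, harmonic_coefficients, simulate_trajectory,
        )

        cfg = SimulationConfig(seed=6, duration=730 * DAY)
        coeffs = harmonic_coefficients(cfg.site_template, 2, skew=cfg.migration_skew)
        m = MovementModel("OUF", sigma2=cfg.sigma2, tau_pos=cfg.tau_pos, tau_v=cfg.tau_v,
                          n_harmonics=2, mean_coeffs=coeffs)
        expected = periodicity(m)
        traj = simulate_trajectory(cfg, "x", rng=np.random.default_rng(66), migratory=True)
        total_var = np.mean([traj.x.var(), traj.y.var()])
        v_m = np.mean((coeffs[:, 1:] ** 2).sum(axis=1) / 2.0)
        mc = 100.0 * v_m / total_var
        assert expected == pytest.approx(mc, rel=0.1)


class TestRmspe:
    def test_harmonic_trend_preferred_for_migratory_bird(self, gps_bird):
        _, _, series = gps_bird
        m0 = fit_family(series, "OU", n_harmonics=0, compute_cov=False)
        m2 = fit_family(series, "OU", n_harmonics=2, compute_cov=False)
        assert rmspe_cv(series, m2) < rmspe_cv(series, m0)
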