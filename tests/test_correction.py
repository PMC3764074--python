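"""Parameter bootstrap: sampling density, replicate simulation, bias/SE,
common-random-number contracts, SIMEX extrapolation."""

import numpy as np
import pytest

from plskrige import ScenarioConfig, generate_study
from plskrige.correction import (BootstrapConfig, BootstrapInputs,
                                 ReplicateSimulator, fit_bias_curve,
                                 parameter_bootstrap,
                                 partial_parametric_bootstrap,
                                 sampling_density, simex_bias)
from plskrige.exposure import ExposureModel, monitor_design, subject_design
from plskrige.health import fit_health_ols
from plskrige.kriging import KrigingFit
from plskrige.pls import project_scores


def _fitted_inputs(scenario="s_like", n_monitors=60, n_subjects=80, seed=7):
    cfg = getattr(ScenarioConfig, scenario)(
        n_monitors=n_monitors, n_subjects=n_subjects, seed=seed)
    st = generate_study(cfg)
    model = ExposureModel(n_components=2, method="pls_uk",
                          compute_param_cov=True)
    model.fit(monitor_design(st.monitor_set, st.covariates_monitors),
              st.monitor_set.conc_sqrt)
    preds = model.predict_full(subject_design(st.subject_coords,
                                              st.covariates_subjects))
    hf = fit_health_ols(st.health_outcomes, preds.pred_raw,
                        st.adjustment_covariates)
    scores_sub = project_scores(model.pls_,
                                model.prep_.transform(st.covariates_subjects))
    return BootstrapInputs(
        kriging_fit=model.kriging_, health_fit=hf,
        coords_monitors=st.monitor_set.coords,
        scores_monitors=model.scores_,
        coords_subjects=st.subject_coords, scores_subjects=scores_sub,
        Z=st.adjustment_covariates.to_numpy()), hf


@pytest.fixture(scope="module")
def fitted():
    return _fitted_inputs()


class TestSamplingDensity:
    def test_mean_is_estimates_on_log_scale(self, fitted):
        inputs, _ = fitted
        mean, cov = sampling_density(inputs.kriging_fit)
        k1 = inputs.kriging_fit.alpha.size
        np.testing.assert_allclose(mean[:k1], inputs.kriging_fit.alpha)
        np.testing.assert_allclose(np.exp(mean[k1:]),
                                   inputs.kriging_fit.theta)

    def test_lambda_scaled_draw_covariance(self, fitted, rng):
        """Draws with covariance lam*Sigma have matching sample covariance."""
        inputs, _ = fitted
        mean, cov = sampling_density(inputs.kriging_fit)
        from plskrige.correction import _psd_sqrt
        L = _psd_sqrt(cov)
        lam = 2.5
        draws = mean + np.sqrt(lam) * (
            rng.standard_normal((5000, mean.size)) @ L.T)
        sample_var = draws.var(axis=0, ddof=1)
        target = lam * np.diag(cov)
        big = target > 1e-8 * np.max(target)
        rel = np.abs(sample_var[big] - target[big]) / target[big]
        assert np.max(rel) < 0.15

    def test_theta_draws_positive_after_back_transform(self, fitted, rng):
        inputs, _ = fitted
        mean, cov = sampling_density(inputs.kriging_fit)
        from plskrige.correction import _psd_sqrt
        L = _psd_sqrt(cov)
        k1 = inputs.kriging_fit.alpha.size
        draws = mean + rng.standard_normal((200, mean.size)) @ L.T
        assert np.all(np.exp(draws[:, k1:]) > 0)


class TestReplicateSimulator:
    def test_outcomes_deterministic_without_residual_noise(self, fitted):
        inputs, hf = fitted
        import dataclasses
        hf0 = dataclasses.replace(hf, sigma_resid=0.0)
        inp0 = dataclasses.replace(inputs, health_fit=hf0)
        sim = ReplicateSimulator(inp0)
        r1 = sim.simulate(np.random.default_rng(5))
        # rebuild with identical stream: identical y because no extra noise
        r2 = ReplicateSimulator(inp0).simulate(np.random.default_rng(5))
        np.testing.assert_array_equal(r1[2], r2[2])
        W = np.clip(r1[1], 0, None) ** 2
        D = np.column_stack([np.ones(len(W)), W, inp0.Z])
        np.testing.assert_allclose(r1[2], D @ sim.beta_hat, atol=1e-12)

    def test_marginal_variance_matches_fitted_sill(self, fitted):
        inputs, _ = fitted
        sim = ReplicateSimulator(inputs)
        rng = np.random.default_rng(3)
        draws = np.array([sim.simulate(rng)[0] for _ in range(300)])
        resid_var = draws.var(axis=0, ddof=1)
        tau2, sigma2, _ = inputs.kriging_fit.theta
        assert abs(resid_var.mean() - (tau2 + sigma2)) < 0.3 * (tau2 + sigma2)

    def test_nugget_only_model_gives_uncorrelated_sites(self):
        """With sigma2=0 in the fitted model, simulated residuals at distinct
        sites are uncorrelated across replicates."""
        inputs, _ = _fitted_inputs(n_monitors=40, n_subjects=20, seed=3)
        import dataclasses
        kf = inputs.kriging_fit
        kf0 = KrigingFit(family=kf.family, theta=(kf.theta[0] + kf.theta[1],
                                                  0.0, kf.theta[2]),
                         alpha=kf.alpha, param_cov=kf.param_cov,
                         loglik=kf.loglik, n_obs=kf.n_obs)
        inp0 = dataclasses.replace(inputs, kriging_fit=kf0)
        sim = ReplicateSimulator(inp0)
        rng = np.random.default_rng(11)
        draws = np.array([sim.simulate(rng)[0] for _ in range(300)])
        corr = np.corrcoef(draws.T)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.percentile(np.abs(off), 95) < 0.2


class TestParameterBootstrap:
    def test_lambda_zero_bias_is_exactly_zero(self, fitted):
        inputs, _ = fitted
        res = parameter_bootstrap(BootstrapConfig(B=50, lam=0.0, seed=1),
                                  inputs)
        assert res.bias == 0.0
        np.testing.assert_array_equal(res.beta_draws, res.beta_draws_lambda0)

    def test_partial_bootstrap_matches_lambda_zero_bitwise(self, fitted):
        inputs, _ = fitted
        a = parameter_bootstrap(BootstrapConfig(B=40, lam=0.0, seed=9), inputs)
        b = partial_parametric_bootstrap(BootstrapConfig(B=40, lam=1.0, seed=9),
                                         inputs)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)

    def test_reproducible_given_seed(self, fitted):
        inputs, _ = fitted
        a = parameter_bootstrap(BootstrapConfig(B=30, lam=1.0, seed=4), inputs)
        b = parameter_bootstrap(BootstrapConfig(B=30, lam=1.0, seed=4), inputs)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        assert a.se_boot == b.se_boot

    def test_common_random_numbers_align_lambda_runs(self, fitted):
        """The lam>0 run and its internal baseline share replicate streams,
        so the paired difference has far smaller variance than either draw."""
        inputs, _ = fitted
        res = parameter_bootstrap(BootstrapConfig(B=200, lam=1.0, seed=2),
                                  inputs)
        paired_sd = np.std(res.beta_draws - res.beta_draws_lambda0, ddof=1)
        assert paired_sd < 0.5 * res.se_boot

    def test_corrected_estimate_identity(self, fitted):
        inputs, hf = fitted
        res = parameter_bootstrap(BootstrapConfig(B=60, lam=1.0, seed=6),
                                  inputs)
        assert res.beta_corrected == pytest.approx(hf.beta_x - res.bias)
        assert res.se_boot >= 0 and res.mc_se > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BootstrapConfig(B=1)
        with pytest.raises(ValueError):
            BootstrapConfig(lam=-0.5)
        with pytest.raises(ValueError):
            BootstrapConfig(lambda_grid=(0.5, 1.0))


class TestSimex:
    def test_quadratic_fit_recovers_exactly_linear_bias(self):
        grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        slope = 0.0123
        coefs = fit_bias_curve(grid, slope * grid, degree=2)
        assert abs(np.polyval(coefs, 1.0) - slope) < 1e-6
        assert abs(coefs[0]) < 1e-10  # no curvature fitted

    def test_degree_must_be_below_grid_size(self):
        with pytest.raises(ValueError):
            fit_bias_curve([0.0, 1.0], [0.0, 0.1], degree=2)

    def test_three_point_grid_reproduces_direct_bias(self, fitted):
        """Quadratic through {0, 0.5, 1} passes through the directly computed
        Bias_1, and near-zero biases leave the estimate at the naive value."""
        inputs, hf = fitted
        cfg = BootstrapConfig(B=120, lam=1.0, seed=5,
                              lambda_grid=(0.0, 0.5, 1.0))
        sx = simex_bias(cfg, inputs, target_lambda=1.0)
        assert sx.bias_at_target == pytest.approx(sx.biases[-1], abs=1e-12)
        direct = parameter_bootstrap(cfg, inputs)
        assert sx.biases[-1] == pytest.approx(direct.bias, abs=1e-12)
        if np.all(np.abs(sx.biases) < 0.1 * direct.se_boot):
            assert sx.beta_corrected == pytest.approx(
                hf.beta_x, abs=0.2 * direct.se_boot)
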