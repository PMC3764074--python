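"""Profile-ML universal kriging: likelihood oracles, conditional means,
invariances, and an external reference-implementation cross-check."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

from plskrige.containers import MonitorSet
from plskrige.kriging import (UniversalKrigingRegressor, fit_universal_kriging,
                              joint_negloglik, kriging_variance,
                              nearest_monitor, predict_uk, profile_negloglik)
from plskrige.synthetic import ScenarioConfig, generate_locations, \
    generate_true_surface
from plskrige.variogram import covariance_matrix, cross_covariance


def _sim_field(seed, n=60, theta=(0.05, 0.2, 300.0), region=1000.0,
               family="exponential"):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, region, (n, 2))
    scores = rng.standard_normal((n, 2))
    cfg = ScenarioConfig(theta_true=theta, variogram_family=family,
                         region_size=region, alpha_true=(0.5, 0.3, -0.2),
                         seed=seed)
    x = generate_true_surface(coords, scores, cfg, rng)
    return coords, scores, x


class TestProfileLikelihood:
    def test_independence_limit_matches_iid_closed_form(self, rng):
        """With sigma2=0 the profile likelihood is the iid Gaussian likelihood
        of the OLS residuals at variance tau2."""
        coords = rng.uniform(0, 100, (40, 2))
        scores = rng.standard_normal((40, 2))
        y = 0.3 + scores @ [0.5, -0.2] + 0.4 * rng.standard_normal(40)
        tau2 = 0.16
        got = profile_negloglik((tau2, 0.0, 50.0), scores, y, coords,
                                "exponential")
        T = np.column_stack([np.ones(40), scores])
        beta, *_ = np.linalg.lstsq(T, y, rcond=None)
        rss = np.sum((y - T @ beta) ** 2)
        expect = 0.5 * (40 * np.log(2 * np.pi * tau2) + rss / tau2)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_translation_invariance_with_intercept(self, rng):
        coords, scores, x = _sim_field(3)
        theta = (0.05, 0.2, 250.0)
        a = profile_negloglik(theta, scores, x, coords, "exponential")
        b = profile_negloglik(theta, scores, x + 5.0, coords, "exponential")
        assert a == pytest.approx(b, abs=1e-7)

    def test_profile_equals_joint_minimized_over_alpha(self):
        """Profiling alpha by GLS matches numeric minimization of the joint
        likelihood over alpha (small-instance oracle)."""
        coords, scores, x = _sim_field(5, n=25)
        theta = np.array([0.06, 0.15, 280.0])
        prof = profile_negloglik(theta, scores, x, coords, "exponential")

        def f(alpha):
            return joint_negloglik(alpha, np.log(theta), scores, x, coords,
                                   "exponential")
        res = optimize.minimize(f, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        assert prof == pytest.approx(res.fun, abs=1e-6)

    def test_invariant_to_site_reordering(self, rng):
        coords, scores, x = _sim_field(8, n=30)
        theta = (0.05, 0.2, 300.0)
        perm = rng.permutation(30)
        a = profile_negloglik(theta, scores, x, coords, "exponential")
        b = profile_negloglik(theta, scores[perm], x[perm], coords[perm],
                              "exponential")
        assert a == pytest.approx(b, rel=1e-10)

    def test_invalid_theta_rejected(self, rng):
        coords, scores, x = _sim_field(1, n=20)
        with pytest.raises(ValueError):
            profile_negloglik((-0.1, 0.2, 10.0), scores, x, coords,
                              "exponential")


class TestFit:
    def test_fitted_theta_beats_surrounding_grid(self):
        coords, scores, x = _sim_field(21, n=50)
        kf = fit_universal_kriging(scores, x, coords)
        nll_hat = -kf.loglik
        factors = (0.5, 0.8, 1.0, 1.25, 2.0)
        for ft in factors:
            for fs in factors:
                for fp in factors:
                    theta = (kf.theta[0] * ft + 1e-12,
                             kf.theta[1] * fs + 1e-12,
                             kf.theta[2] * fp)
                    val = profile_negloglik(theta, scores, x, coords,
                                            "exponential")
                    assert nll_hat <= val + 1e-6

    def test_matches_nlme_gls_reference(self, tmp_path):
        """The profile-ML optimum agrees with R nlme::gls (ML, exponential
        correlation with nugget) on a shared dataset."""
        coords, scores, x = _sim_field(17, n=60)
        kf = fit_universal_kriging(scores, x, coords)
        csv = tmp_path / "field.csv"
        pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                      "s1": scores[:, 0], "s2": scores[:, 1],
                      "v": x}).to_csv(csv, index=False)
        rcode = f"""
suppressMessages(library(nlme))
d <- read.csv("{csv}")
m <- gls(v ~ s1 + s2, data=d,
         correlation=corExp(form=~x+y, nugget=TRUE), method="ML")
cat(sprintf("%.8f", logLik(m)), "\\n")
"""
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ll_r = float(out.stdout.strip().split()[-1])
        assert kf.loglik == pytest.approx(ll_r, abs=5e-2)

    def test_too_few_monitors_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_universal_kriging(rng.standard_normal((4, 2)), np.ones(4),
                                  rng.uniform(0, 10, (4, 2)))

    def test_param_cov_is_symmetric_psd(self):
        coords, scores, x = _sim_field(31, n=40)
        kf = fit_universal_kriging(scores, x, coords, compute_param_cov=True)
        C = kf.param_cov
        assert np.allclose(C, C.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-10


class TestPrediction:
    def test_conditional_mean_oracle_small_instances(self):
        """predict_uk equals the direct joint-Gaussian conditional mean
        computed from the full covariance matrix."""
        rng = np.random.default_rng(2024)
        from plskrige.kriging import KrigingFit
        for rep in range(5):
            n_obs, n_new = 30, 8
            coords_obs = rng.uniform(0, 500, (n_obs, 2))
            coords_new = rng.uniform(0, 500, (n_new, 2))
            scores_obs = rng.standard_normal((n_obs, 2))
            scores_new = rng.standard_normal((n_new, 2))
            theta = (rng.uniform(0.01, 0.2), rng.uniform(0.1, 0.5),
                     rng.uniform(50, 400))
            alpha = rng.standard_normal(3)
            y = rng.standard_normal(n_obs)
            kf = KrigingFit(family="exponential", theta=theta, alpha=alpha,
                            param_cov=np.eye(6), loglik=0.0, n_obs=n_obs)
            pred = predict_uk(kf, scores_new, coords_new, scores_obs, y,
                              coords_obs).pred_sqrt
            # oracle: joint covariance over [obs, new]
            allc = np.vstack([coords_obs, coords_new])
            S = covariance_matrix(theta, cdist(allc, allc), "exponential")
            S_oo = S[:n_obs, :n_obs]
            # cross block without nugget: distinct sites
            S_no = cross_covariance(theta, coords_new, coords_obs,
                                    "exponential")
            mu_obs = np.column_stack([np.ones(n_obs), scores_obs]) @ alpha
            mu_new = np.column_stack([np.ones(n_new), scores_new]) @ alpha
            oracle = mu_new + S_no @ np.linalg.solve(S_oo, y - mu_obs)
            assert np.max(np.abs(pred - oracle)) < 1e-8

    def test_exact_interpolation_without_nugget(self, rng):
        from plskrige.kriging import KrigingFit
        coords = rng.uniform(0, 300, (25, 2))
        scores = rng.standard_normal((25, 1))
        y = rng.standard_normal(25)
        kf = KrigingFit(family="exponential", theta=(0.0, 0.3, 150.0),
                        alpha=np.array([0.1, 0.2]), param_cov=np.eye(5),
                        loglik=0.0, n_obs=25)
        pred = predict_uk(kf, scores, coords, scores, y, coords).pred_sqrt
        assert np.max(np.abs(pred - y)) < 1e-7

    def test_no_spatial_limit_returns_regression_mean(self, rng):
        from plskrige.kriging import KrigingFit
        coords = rng.uniform(0, 300, (20, 2))
        scores = rng.standard_normal((20, 1))
        y = rng.standard_normal(20)
        kf = KrigingFit(family="exponential", theta=(0.2, 0.0, 150.0),
                        alpha=np.array([0.1, 0.5]), param_cov=np.eye(5),
                        loglik=0.0, n_obs=20)
        new_scores = rng.standard_normal((6, 1))
        new_coords = rng.uniform(0, 300, (6, 2))
        pred = predict_uk(kf, new_scores, new_coords, scores, y,
                          coords).pred_sqrt
        expect = np.column_stack([np.ones(6), new_scores]) @ kf.alpha
        assert np.allclose(pred, expect, atol=1e-12)

    def test_remote_site_reverts_to_mean(self, rng):
        from plskrige.kriging import KrigingFit
        coords = rng.uniform(0, 100, (15, 2))
        scores = rng.standard_normal((15, 1))
        y = rng.standard_normal(15)
        kf = KrigingFit(family="exponential", theta=(0.05, 0.3, 20.0),
                        alpha=np.array([0.4, 0.1]), param_cov=np.eye(5),
                        loglik=0.0, n_obs=15)
        far = np.array([[1e6, 1e6]])
        s_new = np.array([[0.7]])
        pred = predict_uk(kf, s_new, far, scores, y, coords).pred_sqrt
        expect = kf.alpha[0] + 0.7 * kf.alpha[1]
        assert abs(pred[0] - expect) < 1e-6

    def test_adding_a_monitor_never_increases_conditional_variance(self, rng):
        from plskrige.kriging import KrigingFit
        kf = KrigingFit(family="exponential", theta=(0.05, 0.3, 100.0),
                        alpha=np.array([0.0]), param_cov=np.eye(4),
                        loglik=0.0, n_obs=10)
        coords = rng.uniform(0, 300, (10, 2))
        target = rng.uniform(0, 300, (5, 2))
        v_before = kriging_variance(kf, target, coords)
        extra = rng.uniform(0, 300, (1, 2))
        v_after = kriging_variance(kf, target, np.vstack([coords, extra]))
        assert np.all(v_after <= v_before + 1e-10)


class TestNearestMonitor:
    def test_coincident_site_gets_that_monitor(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        conc = np.array([1.0, 2.0])
        pred = nearest_monitor(coords, conc, np.array([[10.0, 0.0]]))
        assert pred.pred_sqrt[0] == 2.0

    def test_tie_broken_by_lowest_id(self):
        coords = np.array([[-1.0, 0.0], [1.0, 0.0]])
        conc = np.array([5.0, 9.0])
        pred = nearest_monitor(coords, conc, np.array([[0.0, 0.0]]),
                               monitor_ids=np.array([7, 2]))
        assert pred.pred_sqrt[0] == 9.0  # monitor id 2 wins the tie

    def test_no_monitors_rejected(self):
        with pytest.raises(ValueError):
            nearest_monitor(np.empty((0, 2)), np.empty(0),
                            np.array([[0.0, 0.0]]))


class TestEstimatorFacade:
    def test_regressor_fit_predict_round_trip(self):
        coords, scores, x = _sim_field(9, n=40)
        X = np.column_stack([coords, scores])
        est = UniversalKrigingRegressor(compute_param_cov=False).fit(X, x)
        assert est.theta_[2] > 0
        pred = est.predict(X)
        # kriging with a nugget shrinks toward the mean but tracks the data
        assert np.corrcoef(pred, x)[0, 1] > 0.5
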