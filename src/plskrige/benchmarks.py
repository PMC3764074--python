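"""Reusable validation experiments at desk scale.

These routines regenerate the package's headline quality checks from
scratch: conditional-mean oracle agreement, profile-likelihood optimality,
variogram-parameter recovery, cross-validated prediction accuracy, and the
measurement-error phenomenology of the parameter bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .correction import BootstrapConfig, BootstrapInputs, parameter_bootstrap
from .evaluation import cross_validate, cv_table
from .exposure import ExposureModel, monitor_design, subject_design
from .health import fit_health_ols
from .kriging import (KrigingFit, fit_universal_kriging, predict_uk,
                      profile_negloglik)
from .pls import project_scores
from .synthetic import (ScenarioConfig, generate_locations,
                        generate_true_surface, generate_study)
from .variogram import covariance_matrix, cross_covariance


def kriging_oracle_errors(n_instances: int = 20, n_obs: int = 30,
                          n_new: int = 8, seed: int = 0):
    """Max |predict_uk − direct joint-Gaussian conditional mean| over random
    instances, plus the max interpolation error at monitors when τ² = 0."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    max_interp = 0.0
    for _ in range(n_instances):
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
        S_oo = covariance_matrix(theta, cdist(coords_obs, coords_obs),
                                 "exponential")
        S_no = cross_covariance(theta, coords_new, coords_obs, "exponential")
        mu_o = np.column_stack([np.ones(n_obs), scores_obs]) @ alpha
        mu_n = np.column_stack([np.ones(n_new), scores_new]) @ alpha
        oracle = mu_n + S_no @ np.linalg.solve(S_oo, y - mu_o)
        max_err = max(max_err, float(np.max(np.abs(pred - oracle))))

        kf0 = KrigingFit(family="exponential",
                         theta=(0.0, theta[1], theta[2]), alpha=alpha,
                         param_cov=np.eye(6), loglik=0.0, n_obs=n_obs)
        interp = predict_uk(kf0, scores_obs, coords_obs, scores_obs, y,
                            coords_obs).pred_sqrt
        max_interp = max(max_interp, float(np.max(np.abs(interp - y))))
    return max_err, max_interp


def _direct_field(cfg: ScenarioConfig, n: int, seed: int):
    """Monitor geometry + iid scores + one surface draw from the joint model."""
    rng = np.random.default_rng(seed)
    coords, _ = generate_locations(cfg, rng)
    scores = rng.standard_normal((n, 2))
    x = generate_true_surface(coords, scores, cfg, rng)
    return coords, scores, x


def grid_optimality_margin(n_fields: int = 3, n: int = 50, seed: int = 0,
                           factors=(0.5, 0.75, 1.0, 1.5, 2.5)) -> float:
    """Min over fields and a 5×5×5 multiplicative grid around θ̂ of
    (profile nll at grid point − profile nll at θ̂); ≥ 0 up to optimizer
    tolerance when the fit is optimal."""
    margin = np.inf
    for i in range(n_fields):
        cfg = ScenarioConfig(theta_true=(0.05, 0.2, 300.0),
                             region_size=1000.0, n_monitors=n,
                             alpha_true=(0.5, 0.3, -0.2), seed=seed + i)
        coords, scores, x = _direct_field(cfg, n, seed + i)
        kf = fit_universal_kriging(scores, x, coords)
        nll_hat = -kf.loglik
        for ft in factors:
            for fs in factors:
                for fp in factors:
                    theta = (kf.theta[0] * ft + 1e-12,
                             kf.theta[1] * fs + 1e-12, kf.theta[2] * fp)
                    val = profile_negloglik(theta, scores, x, coords,
                                            kf.family)
                    margin = min(margin, val - nll_hat)
    return float(margin)


def recovery_experiment(scenario: str = "s_like", n_monitors: int = 300,
                        n_replicates: int = 20, seed: int = 0) -> np.ndarray:
    """Fitted θ̂ over replicate fields simulated from the scenario's spatial
    model (iid scores, so the mean structure is exactly as assumed)."""
    thetas = []
    for i in range(n_replicates):
        cfg = getattr(ScenarioConfig, scenario)(n_monitors=n_monitors,
                                                seed=seed + i)
        coords, scores, x = _direct_field(cfg, n_monitors, seed + i)
        kf = fit_universal_kriging(scores, x, coords,
                                   compute_param_cov=False)
        thetas.append(kf.theta)
    return np.asarray(thetas)


@dataclass
class PhenomenologyRun:
    """One study realization's naive vs bootstrap inference summary."""

    scenario: str
    study_seed: int
    naive_se: float
    se_lambda1: float
    se_lambda0: float
    bias: float
    mc_se: float
    mc_se_bias: float
    beta_naive: float


def fit_two_stage(study, n_components: int = 2, family: str = "exponential"):
    """Fit stage 1 + stage 2 on a synthetic study; returns (model, health
    fit, bootstrap inputs)."""
    model = ExposureModel(n_components=n_components, family=family,
                          method="pls_uk", compute_param_cov=True)
    model.fit(monitor_design(study.monitor_set, study.covariates_monitors),
              study.monitor_set.conc_sqrt)
    preds = model.predict_full(subject_design(study.subject_coords,
                                              study.covariates_subjects))
    hf = fit_health_ols(study.health_outcomes, preds.pred_raw,
                        study.adjustment_covariates)
    scores_sub = project_scores(
        model.pls_, model.prep_.transform(study.covariates_subjects))
    inputs = BootstrapInputs(
        kriging_fit=model.kriging_, health_fit=hf,
        coords_monitors=study.monitor_set.coords,
        scores_monitors=model.scores_,
        coords_subjects=study.subject_coords,
        scores_subjects=scores_sub,
        Z=study.adjustment_covariates.to_numpy())
    return model, hf, inputs


def bootstrap_phenomenology(scenario: str, study_seeds=(0, 1, 2),
                            n_monitors: int = 150, n_subjects: int = 500,
                            B: int = 1000, seed: int = 0):
    """Parameter-bootstrap SEs vs naive SEs over replicate study
    realizations of a scenario (each run yields the λ=1 and paired λ=0
    summaries on common random numbers)."""
    runs = []
    for s in study_seeds:
        cfg = getattr(ScenarioConfig, scenario)(
            n_monitors=n_monitors, n_subjects=n_subjects, seed=int(s))
        study = generate_study(cfg)
        _, hf, inputs = fit_two_stage(study)
        res = parameter_bootstrap(
            BootstrapConfig(B=B, lam=1.0, seed=seed + int(s)), inputs)
        runs.append(PhenomenologyRun(
            scenario=scenario, study_seed=int(s),
            naive_se=hf.se["exposure"], se_lambda1=res.se_boot,
            se_lambda0=res.se_boot_lambda0, bias=res.bias,
            mc_se=res.mc_se, mc_se_bias=res.mc_se_bias,
            beta_naive=hf.beta_x))
    return runs


def cv_benchmark(scenario: str = "s_like", n_monitors: int = 150,
                 k_grid=(1, 2, 3), seed: int = 0):
    """Cross-validated RMSEP/R² table over pls_only / pls_uk /
    nearest_monitor for one scenario realization."""
    cfg = getattr(ScenarioConfig, scenario)(n_monitors=n_monitors,
                                            n_subjects=10, seed=seed)
    study = generate_study(cfg)
    results = cross_validate(
        study.monitor_set, study.covariates_monitors,
        methods=("pls_only", "pls_uk", "nearest_monitor"),
        k_grid=k_grid, n_folds=10, seed=seed)
    return cv_table(results), results
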