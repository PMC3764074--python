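"""Measurement-error correction by the parameter bootstrap and SIMEX.

The two-stage analysis predicts exposures (smoothing ⇒ Berkson-like error)
with estimated exposure-model parameters (⇒ classical-like error). The
parameter bootstrap propagates both into the health coefficient:

1. Estimate a multivariate-normal sampling density for (α̂, log θ̂) from the
   observed information of the exposure-model likelihood.
2. For each replicate j: simulate monitor observations and true subject
   exposures jointly from the fitted spatial model and health outcomes from
   the fitted disease model; draw parameters (α_j, θ_j) from the density
   with covariance scaled by λ ≥ 0; re-predict subject exposures by
   universal kriging with the drawn parameters applied to the simulated
   monitor data; re-fit the OLS disease model for β̂_x,j.
3. Bias_λ = E_λ(β̂_x) − E_0(β̂_x) (common random numbers across λ);
   corrected estimate = naive β̂_x − Bias_λ.
4. Bootstrap SE = sample SD of the replicate β̂_x,j.

λ = 0 is the partial parametric bootstrap (Berkson-like error only).
SIMEX evaluates Bias_λ on a λ grid with shared replicate streams and
extrapolates a polynomial trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

from .health import HealthFit
from .kriging import KrigingFit, _chol_jitter, _design
from .variogram import covariance_matrix, cross_covariance

logger = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Replication settings for the parameter bootstrap / SIMEX."""

    B: int = 1000
    lam: float = 1.0
    seed: int = 0
    lambda_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    extrapolant_degree: int = 2
    max_drop_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        grid = tuple(float(l) for l in self.lambda_grid)
        if sorted(grid) != list(grid) or 0.0 not in grid:
            raise ValueError("lambda_grid must be sorted and contain 0")
        self.lambda_grid = grid


@dataclass
class BootstrapInputs:
    """Everything the bootstrap needs from the fitted two-stage model."""

    kriging_fit: KrigingFit
    health_fit: HealthFit
    coords_monitors: np.ndarray
    scores_monitors: np.ndarray
    coords_subjects: np.ndarray
    scores_subjects: np.ndarray
    Z: np.ndarray


@dataclass
class BootstrapResult:
    """Replicate draws and derived bias / SE summaries at one λ."""

    lam: float
    beta_draws: np.ndarray          # β̂_x,j at λ
    beta_draws_lambda0: np.ndarray  # paired baseline draws (fixed parameters)
    mean_lambda: float
    mean_lambda0: float
    bias: float
    beta_naive: float
    beta_corrected: float
    se_boot: float
    se_boot_lambda0: float
    mc_se: float                    # MC error of se_boot
    mc_se_bias: float               # MC error of the bias estimate
    n_dropped: int


@dataclass
class SimexResult:
    lambda_grid: tuple
    biases: np.ndarray
    poly_coefs: np.ndarray
    bias_at_target: float
    target_lambda: float
    beta_naive: float
    beta_corrected: float


def sampling_density(kf: KrigingFit):
    """MVN sampling density for (α̂, log θ̂): (mean, covariance)."""
    mean = np.concatenate([kf.alpha, np.log(np.asarray(kf.theta))])
    cov = 0.5 * (kf.param_cov + kf.param_cov.T)
    w, V = np.linalg.eigh(cov)
    if np.min(w) < -1e-10 * max(np.max(w), 1.0):
        warnings.warn("param_cov not PSD; projecting to nearest PSD matrix")
    w = np.clip(w, 0.0, None)
    cov = (V * w) @ V.T
    return mean, 0.5 * (cov + cov.T)


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    return V * np.sqrt(np.clip(w, 0.0, None))


class ReplicateSimulator:
    """Pre-factorized machinery for bootstrap replicates.

    Holds the joint (monitors + subjects) Cholesky factor at the point
    estimates and the monitor-covariance solve operator used by the fixed-
    parameter (λ = 0) predictions.
    """

    def __init__(self, inputs: BootstrapInputs):
        self.inp = inputs
        kf = inputs.kriging_fit
        self.T_obs = _design(inputs.scores_monitors)
        self.T_new = _design(inputs.scores_subjects)
        self.n_mon = self.T_obs.shape[0]
        self.n_sub = self.T_new.shape[0]
        coords_all = np.vstack([inputs.coords_monitors, inputs.coords_subjects])
        D_all = cdist(coords_all, coords_all)
        cov_all = covariance_matrix(kf.theta, D_all, kf.family)
        self.L_all = np.linalg.cholesky(
            cov_all + 1e-12 * np.mean(np.diag(cov_all))
            * np.eye(cov_all.shape[0]))
        self.mean_all = np.concatenate([self.T_obs @ kf.alpha,
                                        self.T_new @ kf.alpha])
        self.D_obs = cdist(inputs.coords_monitors, inputs.coords_monitors)
        sigma_obs = covariance_matrix(kf.theta, self.D_obs, kf.family)
        self._cho_point = _chol_jitter(sigma_obs)
        self.C_point = cross_covariance(kf.theta, inputs.coords_subjects,
                                        inputs.coords_monitors, kf.family)
        self.d_cross = cdist(inputs.coords_subjects, inputs.coords_monitors)
        hf = inputs.health_fit
        self.beta_hat = np.concatenate([[hf.beta0, hf.beta_x], hf.beta_z])
        Z = np.asarray(inputs.Z, dtype=float)
        self.Z = Z if Z.ndim == 2 else Z[:, None]

    def simulate(self, rng: np.random.Generator):
        """One joint draw of (monitor obs, true subject exposures, outcomes)."""
        z = rng.standard_normal(self.n_mon + self.n_sub)
        x_all = self.mean_all + self.L_all @ z
        x_mon, x_sub = x_all[:self.n_mon], x_all[self.n_mon:]
        W_true = np.clip(x_sub, 0.0, None) ** 2
        design = np.column_stack([np.ones(self.n_sub), W_true, self.Z])
        y = design @ self.beta_hat
        sig = self.inp.health_fit.sigma_resid
        if sig > 0:
            y = y + sig * rng.standard_normal(self.n_sub)
        return x_mon, x_sub, y

    def predict_point(self, x_mon: np.ndarray) -> np.ndarray:
        """Kriging prediction at subjects with the point estimates."""
        kf = self.inp.kriging_fit
        resid = x_mon - self.T_obs @ kf.alpha
        return self.T_new @ kf.alpha + self.C_point @ linalg.cho_solve(
            self._cho_point, resid)

    def predict_drawn(self, x_mon: np.ndarray, alpha_j: np.ndarray,
                      theta_j) -> np.ndarray:
        """Kriging prediction at subjects with drawn parameters."""
        kf = self.inp.kriging_fit
        sigma = covariance_matrix(theta_j, self.D_obs, kf.family)
        cho = _chol_jitter(sigma)
        tau2, sigma2, phi = theta_j
        from .variogram import correlation
        C = sigma2 * correlation(kf.family, self.d_cross, phi)
        resid = x_mon - self.T_obs @ alpha_j
        return self.T_new @ alpha_j + C @ linalg.cho_solve(cho, resid)

    def refit_beta(self, W: np.ndarray, y: np.ndarray) -> float:
        design = np.column_stack([np.ones(self.n_sub), W, self.Z])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(coef[1])


def parameter_bootstrap(cfg: BootstrapConfig,
                        inputs: BootstrapInputs) -> BootstrapResult:
    """Steps 2–4 of the parameter bootstrap at λ = ``cfg.lam``.

    Each replicate also produces the paired fixed-parameter (λ = 0) draw on
    the same simulated data, so the bias contrast uses common random
    numbers. At λ = 0 the two passes coincide and the bias is exactly 0.
    """
    sim = ReplicateSimulator(inputs)
    mean, cov = sampling_density(inputs.kriging_fit)
    Lp = _psd_sqrt(cov)
    k1 = inputs.kriging_fit.alpha.size
    root = np.sqrt(cfg.lam)

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    draws_lam, draws_0 = [], []
    n_dropped = 0
    for j in range(cfg.B):
        rng = np.random.default_rng(children[j])
        x_mon, _, y_b = sim.simulate(rng)
        z_par = rng.standard_normal(mean.size)
        try:
            pred0 = sim.predict_point(x_mon)
            if cfg.lam == 0:
                pred_lam = pred0
            else:
                par = mean + root * (Lp @ z_par)
                alpha_j = par[:k1]
                theta_j = tuple(np.exp(par[k1:]))
                pred_lam = sim.predict_drawn(x_mon, alpha_j, theta_j)
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            n_dropped += 1
            continue
        W0 = np.clip(pred0, 0.0, None) ** 2
        Wl = np.clip(pred_lam, 0.0, None) ** 2
        draws_0.append(sim.refit_beta(W0, y_b))
        draws_lam.append(sim.refit_beta(Wl, y_b) if cfg.lam != 0
                         else draws_0[-1])
    if n_dropped > cfg.max_drop_frac * cfg.B:
        raise RuntimeError(
            f"{n_dropped}/{cfg.B} bootstrap replicates failed "
            f"(> {cfg.max_drop_frac:.0%} allowed)")
    if n_dropped:
        logger.warning("dropped %d bootstrap replicates", n_dropped)

    draws_lam = np.asarray(draws_lam)
    draws_0 = np.asarray(draws_0)
    Bu = draws_lam.size
    mean_lam = float(draws_lam.mean())
    mean_0 = float(draws_0.mean())
    bias = mean_lam - mean_0
    beta_naive = inputs.health_fit.beta_x
    se = float(draws_lam.std(ddof=1))
    se0 = float(draws_0.std(ddof=1))
    diff = draws_lam - draws_0
    return BootstrapResult(
        lam=cfg.lam, beta_draws=draws_lam, beta_draws_lambda0=draws_0,
        mean_lambda=mean_lam, mean_lambda0=mean_0, bias=bias,
        beta_naive=beta_naive, beta_corrected=beta_naive - bias,
        se_boot=se, se_boot_lambda0=se0,
        mc_se=se / np.sqrt(2.0 * (Bu - 1)),
        mc_se_bias=float(diff.std(ddof=1) / np.sqrt(Bu)),
        n_dropped=n_dropped)


def partial_parametric_bootstrap(cfg: BootstrapConfig,
                                 inputs: BootstrapInputs) -> BootstrapResult:
    """λ = 0 specialization: Berkson-like error only, parameters fixed."""
    return parameter_bootstrap(replace(cfg, lam=0.0), inputs)


def fit_bias_curve(lambda_grid, biases, degree: int = 2) -> np.ndarray:
    """Polynomial fit of Bias_λ against λ; returns highest-degree-first
    coefficients (np.polyval convention)."""
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    biases = np.asarray(biases, dtype=float)
    if degree >= lambda_grid.size:
        raise ValueError("extrapolant degree must be < grid size")
    return np.polyfit(lambda_grid, biases, degree)


def simex_bias(cfg: BootstrapConfig, inputs: BootstrapInputs,
               target_lambda: float = 1.0) -> SimexResult:
    """Bias_λ over ``cfg.lambda_grid`` with shared replicate streams, plus a
    polynomial extrapolant evaluated at ``target_lambda``."""
    grid = cfg.lambda_grid
    if len(grid) < 3:
        raise ValueError("lambda_grid needs at least 3 values")
    sim = ReplicateSimulator(inputs)
    mean, cov = sampling_density(inputs.kriging_fit)
    Lp = _psd_sqrt(cov)
    k1 = inputs.kriging_fit.alpha.size

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    draws = {lam: [] for lam in grid}
    n_dropped = 0
    for j in range(cfg.B):
        rng = np.random.default_rng(children[j])
        x_mon, _, y_b = sim.simulate(rng)
        z_par = rng.standard_normal(mean.size)
        betas = {}
        try:
            for lam in grid:
                if lam == 0:
                    pred = sim.predict_point(x_mon)
                else:
                    par = mean + np.sqrt(lam) * (Lp @ z_par)
                    pred = sim.predict_drawn(x_mon, par[:k1],
                                             tuple(np.exp(par[k1:])))
                W = np.clip(pred, 0.0, None) ** 2
                betas[lam] = sim.refit_beta(W, y_b)
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            n_dropped += 1
            continue
        for lam in grid:
            draws[lam].append(betas[lam])
    if n_dropped > cfg.max_drop_frac * cfg.B:
        raise RuntimeError(f"{n_dropped}/{cfg.B} SIMEX replicates failed")

    mean0 = float(np.mean(draws[0.0]))
    biases = np.array([float(np.mean(draws[lam])) - mean0 for lam in grid])
    coefs = fit_bias_curve(grid, biases, cfg.extrapolant_degree)
    bias_t = float(np.polyval(coefs, target_lambda))
    beta_naive = inputs.health_fit.beta_x
    return SimexResult(lambda_grid=grid, biases=biases, poly_coefs=coefs,
                       bias_at_target=bias_t, target_lambda=target_lambda,
                       beta_naive=beta_naive,
                       beta_corrected=beta_naive - bias_t)
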