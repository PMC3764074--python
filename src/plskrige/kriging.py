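"""Universal kriging with a PLS-score mean structure, fit by profile ML.

The sqrt-scale concentrations X* at monitor locations follow

    X* = T* α + η*,    η* ~ N(0, Σ(θ)),    Σ(θ) = τ² I + σ² ρ(D/φ),

with T* = [1, scores]. For fixed θ the mean coefficients α have a closed-form
generalized-least-squares solution, so the likelihood is profiled over α and
numerically minimized over (log τ², log σ², log φ) from a multi-start grid.
Predictions at new sites are conditional means of the joint Gaussian model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import ExposurePredictions, floored_square
from .variogram import (FAMILIES, correlation, covariance_matrix,
                        cross_covariance, empirical_semivariogram)

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class KrigingFit:
    """Fitted universal-kriging model.

    ``theta`` = (τ², σ², φ); ``alpha`` = (intercept, score coefficients);
    ``param_cov`` is the joint covariance of (α̂, log θ̂) from the observed
    information of the joint likelihood.
    """

    family: str
    theta: tuple
    alpha: np.ndarray
    param_cov: np.ndarray
    loglik: float
    n_obs: int
    converged: bool = True

    def __post_init__(self) -> None:
        tau2, sigma2, phi = self.theta
        if tau2 < 0 or sigma2 < 0 or phi <= 0:
            raise ValueError("invalid fitted theta")


def _design(scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return np.column_stack([np.ones(scores.shape[0]), scores])


def _chol_jitter(sigma: np.ndarray, tries: int = 4):
    scale = float(np.mean(np.diag(sigma))) or 1.0
    jitter = 0.0
    for t in range(tries):
        try:
            return linalg.cho_factor(
                sigma + jitter * np.eye(sigma.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = 1e-10 * scale * 10 ** t
    raise linalg.LinAlgError("covariance factorization failed after jitter")


def _gls_alpha(cho, T, y):
    Si_T = linalg.cho_solve(cho, T)
    A = T.T @ Si_T
    b = Si_T.T @ y
    return linalg.solve(A, b, assume_a="pos")


def profile_negloglik(theta, scores, conc_sqrt, coords, family: str,
                      dist_matrix: np.ndarray | None = None) -> float:
    """Negative Gaussian log-likelihood with α profiled out by GLS."""
    tau2, sigma2, phi = theta
    if tau2 < 0 or sigma2 < 0 or phi <= 0:
        raise ValueError("theta outside valid domain")
    y = np.asarray(conc_sqrt, dtype=float)
    T = _design(scores)
    n = y.shape[0]
    if dist_matrix is None:
        coords = np.asarray(coords, dtype=float)
        dist_matrix = cdist(coords, coords)
    sigma = covariance_matrix(theta, dist_matrix, family)
    cho = _chol_jitter(sigma)
    alpha = _gls_alpha(cho, T, y)
    r = y - T @ alpha
    quad = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return 0.5 * (n * _LOG2PI + logdet + quad)


def joint_negloglik(alpha, log_theta, scores, conc_sqrt, coords, family: str,
                    dist_matrix: np.ndarray | None = None) -> float:
    """Joint negative log-likelihood in (α, log θ); used for the information
    matrix and as the oracle for profile-likelihood equivalence."""
    theta = tuple(np.exp(np.asarray(log_theta, dtype=float)))
    y = np.asarray(conc_sqrt, dtype=float)
    T = _design(scores)
    n = y.shape[0]
    if dist_matrix is None:
        coords = np.asarray(coords, dtype=float)
        dist_matrix = cdist(coords, coords)
    sigma = covariance_matrix(theta, dist_matrix, family)
    cho = _chol_jitter(sigma)
    r = y - T @ np.asarray(alpha, dtype=float)
    quad = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return 0.5 * (n * _LOG2PI + logdet + quad)


def _start_grid(resid_var: float, dmax: float):
    fracs = (0.05, 0.5, 0.95)
    phis = (0.1, 0.3, 0.9)
    starts = []
    for ft in fracs:
        for fs in fracs:
            for fp in phis:
                starts.append((max(ft * resid_var, 1e-10),
                               max(fs * resid_var, 1e-10),
                               fp * dmax))
    return starts


def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    d = x0.size
    h = rel_step * (1.0 + np.abs(x0))
    H = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                val = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                val = (f(x0 + ei + ej) - f(x0 + ei - ej)
                       - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H

# variances on the (α, log θ) scale are capped so that weakly identified
# directions (e.g. σ² at the zero boundary) give bounded bootstrap draws
_MAX_PARAM_VAR = 25.0


def _param_covariance(scores, y, coords, family, alpha_hat, theta_hat,
                      dist_matrix) -> np.ndarray:
    k1 = alpha_hat.size
    log_theta = np.log(np.asarray(theta_hat))

    def f(x):
        return joint_negloglik(x[:k1], x[k1:], scores, y, coords, family,
                               dist_matrix=dist_matrix)

    x0 = np.concatenate([alpha_hat, log_theta])
    H = _numerical_hessian(f, x0)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    # invert only well-determined curvature; cap resulting variances
    inv_w = np.where(w > 1.0 / _MAX_PARAM_VAR, 1.0 / np.maximum(w, 1e-300),
                     _MAX_PARAM_VAR)
    cov = (V * inv_w) @ V.T
    return 0.5 * (cov + cov.T)


def fit_universal_kriging(scores, conc_sqrt, coords,
                          family: str = "exponential",
                          n_best_starts: int = 3,
                          compute_param_cov: bool = True) -> KrigingFit:
    """Profile-ML fit of θ = (τ², σ², φ) and GLS mean coefficients α.

    Optimization runs on (log τ², log σ², log φ) with L-BFGS-B from the
    best few points of a 3×3×3 start grid derived from the OLS residual
    variance and the maximum inter-site distance; deterministic.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    y = np.asarray(conc_sqrt, dtype=float)
    coords = np.asarray(coords, dtype=float)
    T = _design(scores)
    n, k1 = T.shape
    if n < k1 + 3:
        raise ValueError("too few monitors for the requested mean structure")
    D = cdist(coords, coords)
    dmax = float(np.max(D))
    if dmax <= 0:
        raise ValueError("all sites are coincident")

    beta_ols, *_ = np.linalg.lstsq(T, y, rcond=None)
    resid = y - T @ beta_ols
    resid_var = max(float(resid.var(ddof=1)), 1e-12)

    lb = np.log([1e-8 * resid_var, 1e-8 * resid_var, 1e-3 * dmax])
    ub = np.log([1e2 * resid_var, 1e2 * resid_var, 5e1 * dmax])
    bounds = list(zip(lb, ub))

    def obj(log_theta):
        theta = np.exp(np.clip(log_theta, lb, ub))
        try:
            return profile_negloglik(theta, scores, y, coords, family,
                                     dist_matrix=D)
        except linalg.LinAlgError:
            return 1e10

    starts = [np.clip(np.log(s), lb, ub) for s in _start_grid(resid_var, dmax)]
    vals = np.array([obj(s) for s in starts])
    order = np.argsort(vals)[:max(1, n_best_starts)]

    best = None
    for idx in order:
        res = optimize.minimize(obj, starts[idx], method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-10, "gtol": 1e-8,
                                         "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(
            f"universal kriging failed to converge from all starts "
            f"(family={family}, n={n}, best objective="
            f"{None if best is None else best.fun})")

    theta_hat = tuple(np.exp(np.clip(best.x, lb, ub)))
    sigma = covariance_matrix(theta_hat, D, family)
    cho = _chol_jitter(sigma)
    alpha_hat = _gls_alpha(cho, T, y)
    loglik = -float(best.fun)

    if compute_param_cov:
        param_cov = _param_covariance(scores, y, coords, family,
                                      alpha_hat, np.asarray(theta_hat), D)
    else:
        param_cov = np.eye(k1 + 3)
    return KrigingFit(family=family, theta=theta_hat, alpha=alpha_hat,
                      param_cov=param_cov, loglik=loglik, n_obs=n,
                      converged=bool(best.success))


def predict_uk(kf: KrigingFit, scores_new, coords_new, scores_obs,
               conc_sqrt_obs, coords_obs, ids=None) -> ExposurePredictions:
    """Conditional-mean prediction T α̂ + C Σ⁻¹ (X* − T* α̂)."""
    y = np.asarray(conc_sqrt_obs, dtype=float)
    T_new = _design(scores_new)
    T_obs = _design(scores_obs)
    coords_new = np.asarray(coords_new, dtype=float)
    coords_obs = np.asarray(coords_obs, dtype=float)
    if T_new.shape[1] != kf.alpha.shape[0] or T_obs.shape[1] != kf.alpha.shape[0]:
        raise ValueError("score dimension mismatch with fitted alpha")
    if T_obs.shape[0] != y.shape[0] or coords_obs.shape[0] != y.shape[0]:
        raise ValueError("observation arrays are not row-aligned")
    D = cdist(coords_obs, coords_obs)
    sigma = covariance_matrix(kf.theta, D, kf.family)
    cho = _chol_jitter(sigma)
    resid = y - T_obs @ kf.alpha
    C = cross_covariance(kf.theta, coords_new, coords_obs, kf.family)
    pred_sqrt = T_new @ kf.alpha + C @ linalg.cho_solve(cho, resid)
    pred_raw, n_floored = floored_square(pred_sqrt)
    if n_floored:
        logger.info("floored %d negative sqrt-scale predictions", n_floored)
    if ids is None:
        ids = np.arange(len(pred_sqrt))
    return ExposurePredictions(ids=np.asarray(ids), pred_sqrt=pred_sqrt,
                               pred_raw=pred_raw, method="pls_uk",
                               n_floored=n_floored)


def kriging_variance(kf: KrigingFit, coords_new, coords_obs) -> np.ndarray:
    """Simple-kriging conditional variance (known mean):
    τ² + σ² − c' Σ⁻¹ c at each prediction site."""
    coords_new = np.asarray(coords_new, dtype=float)
    coords_obs = np.asarray(coords_obs, dtype=float)
    D = cdist(coords_obs, coords_obs)
    sigma = covariance_matrix(kf.theta, D, kf.family)
    cho = _chol_jitter(sigma)
    C = cross_covariance(kf.theta, coords_new, coords_obs, kf.family)
    tau2, sigma2, _ = kf.theta
    reduction = np.einsum("ij,ji->i", C, linalg.cho_solve(cho, C.T))
    return tau2 + sigma2 - reduction


def nearest_monitor(coords_obs, conc_obs, coords_new, ids=None,
                    monitor_ids=None) -> ExposurePredictions:
    """Value of the Euclidean-nearest monitor; ties go to the lowest id."""
    coords_obs = np.asarray(coords_obs, dtype=float)
    conc_obs = np.asarray(conc_obs, dtype=float)
    coords_new = np.asarray(coords_new, dtype=float)
    if coords_obs.shape[0] == 0:
        raise ValueError("need at least one monitor")
    if monitor_ids is None:
        monitor_ids = np.arange(coords_obs.shape[0])
    order = np.argsort(np.asarray(monitor_ids), kind="stable")
    d = cdist(coords_new, coords_obs[order])
    nearest = order[np.argmin(d, axis=1)]  # argmin picks first => lowest id
    pred_sqrt = conc_obs[nearest]
    pred_raw, n_floored = floored_square(pred_sqrt)
    if ids is None:
        ids = np.arange(len(pred_sqrt))
    return ExposurePredictions(ids=np.asarray(ids), pred_sqrt=pred_sqrt,
                               pred_raw=pred_raw, method="nearest_monitor",
                               n_floored=n_floored)


class UniversalKrigingRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn facade: X = [x_km, y_km, score_1..score_k] columns.

    ``fit`` estimates (θ, α) by profile ML; ``predict`` returns sqrt-scale
    conditional means given the training observations.
    """

    def __init__(self, family: str = "exponential",
                 compute_param_cov: bool = True):
        self.family = family
        self.compute_param_cov = compute_param_cov

    @staticmethod
    def _split(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n, 2 + k): coords then scores")
        return X[:, :2], X[:, 2:]

    def fit(self, X, y):
        coords, scores = self._split(X)
        self.fit_ = fit_universal_kriging(
            scores, y, coords, family=self.family,
            compute_param_cov=self.compute_param_cov)
        self.coords_, self.scores_, self.y_ = coords, scores, np.asarray(y, float)
        self.theta_ = self.fit_.theta
        self.alpha_ = self.fit_.alpha
        return self

    def predict(self, X) -> np.ndarray:
        coords, scores = self._split(X)
        return predict_uk(self.fit_, scores, coords, self.scores_, self.y_,
                          self.coords_).pred_sqrt
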