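"""Partial least squares mean structure for the exposure model.

Dimension reduction of the (standardized) geographic-covariate matrix R* into
k scores T* = R* H chosen to maximize covariance with the sqrt-scale
concentrations; scores at new locations follow as T = R H. Predictions that
use PLS alone are the fitted values of the OLS regression of the response on
the training scores, and collapse to a single weight vector m with
R m + intercept ≡ PLS-only predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression

from .containers import ExposurePredictions, floored_square


@dataclass
class PLSFit:
    """Fitted PLS decomposition (univariate response, NIPALS).

    ``weights`` is the p × k rotation matrix H with T = (R − x_mean) H;
    ``score_coefs`` are the OLS coefficients of the response on the scores;
    ``m`` is the collapsed p-vector with R m + ``m_intercept`` equal to the
    PLS-only fitted values.
    """

    n_components: int
    columns: list
    weights: np.ndarray        # H, p × k
    x_mean: np.ndarray
    y_mean: float
    score_coefs: np.ndarray    # k
    m: np.ndarray              # p
    m_intercept: float
    scores_train: np.ndarray   # N* × k


def _as_matrix(covariates, columns=None):
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    cols = columns if columns is not None else list(range(arr.shape[1]))
    return arr, cols


def fit_pls(covariates, conc_sqrt, k: int) -> PLSFit:
    """Fit k-component PLS of sqrt-scale concentrations on covariates."""
    R, cols = _as_matrix(covariates)
    y = np.asarray(conc_sqrt, dtype=float)
    n, p = R.shape
    if not 1 <= k <= min(p, n - 1):
        raise ValueError(f"k={k} outside 1..min(p, N*-1)={min(p, n - 1)}")
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(R, y)
    H = pls.x_rotations_
    x_mean = pls._x_mean
    y_mean = float(pls._y_mean[0])
    scores = (R - x_mean) @ H
    # OLS of y on scores; NIPALS scores are orthogonal so this equals the
    # per-component loadings, but solve explicitly for numerical robustness
    G = np.column_stack([np.ones(n), scores])
    coefs, *_ = np.linalg.lstsq(G, y, rcond=None)
    score_coefs = coefs[1:]
    m = H @ score_coefs
    m_intercept = float(coefs[0] - x_mean @ m)
    return PLSFit(n_components=k, columns=cols, weights=H, x_mean=x_mean,
                  y_mean=y_mean, score_coefs=score_coefs, m=m,
                  m_intercept=m_intercept, scores_train=scores)


def project_scores(fit: PLSFit, covariates_new) -> np.ndarray:
    """Scores at new locations: T = (R − x_mean) H."""
    R, cols = _as_matrix(covariates_new)
    if R.shape[1] != fit.weights.shape[0]:
        raise ValueError("covariate column mismatch with fitted PLS")
    if isinstance(covariates_new, pd.DataFrame) and cols != fit.columns:
        raise ValueError("covariate column names differ from fit")
    return (R - fit.x_mean) @ fit.weights


def predict_pls_only(fit: PLSFit, covariates_new,
                     ids=None) -> ExposurePredictions:
    """PLS-only predictions (regression of response on training scores)."""
    scores = project_scores(fit, covariates_new)
    # equivalently R m + m_intercept
    pred_sqrt = scores @ fit.score_coefs + (fit.m_intercept + fit.x_mean @ fit.m)
    pred_raw, n_floored = floored_square(pred_sqrt)
    if ids is None:
        ids = np.arange(len(pred_sqrt))
    return ExposurePredictions(ids=np.asarray(ids), pred_sqrt=pred_sqrt,
                               pred_raw=pred_raw, method="pls_only",
                               n_floored=n_floored)


def pls_weight_vector(fit: PLSFit) -> np.ndarray:
    """The p-vector m with R m + intercept ≡ PLS-only predictions."""
    return fit.m.copy()


class PLSExposure(BaseEstimator, RegressorMixin):
    """scikit-learn facade over :func:`fit_pls` / :func:`predict_pls_only`."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        self.fit_ = fit_pls(X, y, self.n_components)
        return self

    def transform(self, X) -> np.ndarray:
        return project_scores(self.fit_, X)

    def predict(self, X) -> np.ndarray:
        return predict_pls_only(self.fit_, X).pred_sqrt
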