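"""Composite exposure model: preprocessing → PLS scores → universal kriging.

``ExposureModel`` is the end-to-end stage-one estimator. ``X`` is a
DataFrame with projected coordinates in columns "x", "y" (km) and the raw
geographic covariates in the remaining columns; ``y`` is the sqrt-scale
concentration vector. All preprocessing statistics, PLS weights and kriging
parameters are learned in ``fit`` and applied unchanged in ``predict``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .containers import ExposurePredictions, floored_square
from .kriging import (KrigingFit, fit_universal_kriging, nearest_monitor,
                      predict_uk)
from .pls import PLSFit, fit_pls, predict_pls_only, project_scores
from .preprocess import CovariatePreprocessor

METHODS = ("pls_only", "pls_uk", "nearest_monitor")


class ExposureModel(BaseEstimator, RegressorMixin):
    """Two-stage exposure predictor on the sqrt-concentration scale.

    Parameters
    ----------
    n_components : int
        Number of PLS scores in the mean structure.
    family : str
        Variogram family for the kriged residual field.
    method : {"pls_only", "pls_uk", "nearest_monitor"}
        Prediction rule; "nearest_monitor" ignores covariates entirely.
    preprocessor : CovariatePreprocessor or None
        Prototype preprocessor; cloned and refit on the training covariates.
    """

    def __init__(self, n_components: int = 2, family: str = "exponential",
                 method: str = "pls_uk", preprocessor=None,
                 compute_param_cov: bool = False):
        self.n_components = n_components
        self.family = family
        self.method = method
        self.preprocessor = preprocessor
        self.compute_param_cov = compute_param_cov

    @staticmethod
    def _split(X: pd.DataFrame):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with 'x', 'y' + covariates")
        if "x" not in X.columns or "y" not in X.columns:
            raise ValueError("X must contain coordinate columns 'x' and 'y'")
        coords = X[["x", "y"]].to_numpy(dtype=float)
        covs = X.drop(columns=["x", "y"])
        return coords, covs

    def fit(self, X: pd.DataFrame, y):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        y = np.asarray(y, dtype=float)
        coords, covs = self._split(X)
        self.coords_ = coords
        self.y_ = y
        if self.method == "nearest_monitor":
            return self
        proto = self.preprocessor or CovariatePreprocessor()
        self.prep_ = clone(proto).fit(covs)
        covs_std = self.prep_.transform(covs)
        self.pls_ = fit_pls(covs_std, y, self.n_components)
        self.scores_ = self.pls_.scores_train
        if self.method == "pls_uk":
            self.kriging_ = fit_universal_kriging(
                self.scores_, y, coords, family=self.family,
                compute_param_cov=self.compute_param_cov)
        return self

    def predict_full(self, X: pd.DataFrame, ids=None) -> ExposurePredictions:
        coords, covs = self._split(X)
        if self.method == "nearest_monitor":
            return nearest_monitor(self.coords_, self.y_, coords, ids=ids)
        covs_std = self.prep_.transform(covs)
        if self.method == "pls_only":
            pred = predict_pls_only(self.pls_, covs_std, ids=ids)
            return pred
        scores_new = project_scores(self.pls_, covs_std)
        return predict_uk(self.kriging_, scores_new, coords, self.scores_,
                          self.y_, self.coords_, ids=ids)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Sqrt-scale predictions (modeling scale)."""
        return self.predict_full(X).pred_sqrt

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        """Untransformed-scale predictions (floored square)."""
        return self.predict_full(X).pred_raw


def monitor_design(monitor_set, covariates: pd.DataFrame) -> pd.DataFrame:
    """Assemble the estimator's X table from a MonitorSet + covariate table."""
    X = covariates.reset_index(drop=True).copy()
    X.insert(0, "x", monitor_set.coords[:, 0])
    X.insert(1, "y", monitor_set.coords[:, 1])
    return X


def subject_design(coords, covariates: pd.DataFrame) -> pd.DataFrame:
    coords = np.asarray(coords, dtype=float)
    X = covariates.reset_index(drop=True).copy()
    X.insert(0, "x", coords[:, 0])
    X.insert(1, "y", coords[:, 1])
    return X
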