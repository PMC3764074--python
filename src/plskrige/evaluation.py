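"""10-fold cross-validation, RMSEP / cross-validated R², model selection.

RMSEP = sqrt(mean held-out squared error) on the modeling (sqrt) scale and
R² = max(0, 1 − MSE / var(obs)) with the n-denominator variance, so that
R² = 1 − RMSEP²/var(obs) exactly whenever no flooring occurs. All training
statistics (covariate screening, PLS weights, kriging parameters) are
re-estimated within each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .exposure import METHODS, ExposureModel, monitor_design


def assign_folds(n: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Random partition into folds 1..n_folds with sizes differing by ≤ 1."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError("need at least one observation per fold")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, n_folds)
    sizes = [base + (1 if i < extra else 0) for i in range(n_folds)]
    ids = np.repeat(np.arange(1, n_folds + 1), sizes)
    return ids[rng.permutation(n)]


def rmsep(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed/predicted length mismatch")
    if observed.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def cv_r2(observed, predicted) -> float:
    """1 − MSE/var(obs) with n-denominator variance, floored at 0."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed/predicted length mismatch")
    var = float(np.var(observed))
    if var == 0:
        raise ValueError("constant observations: R^2 undefined")
    mse = float(np.mean((observed - predicted) ** 2))
    return max(0.0, 1.0 - mse / var)


@dataclass
class CVResult:
    """Cross-validation summary for one (method, k) candidate."""

    method: str
    k: int
    fold_assignment: np.ndarray
    cv_predictions: np.ndarray
    rmsep: float
    r2: float


def cross_validate(monitor_set, covariates: pd.DataFrame,
                   methods=("pls_only", "pls_uk"), k_grid=range(1, 11),
                   n_folds: int = 10, seed: int = 0,
                   family: str = "exponential",
                   preprocessor=None) -> list[CVResult]:
    """Held-out predictions for every (method, k) over shared random folds.

    ``nearest_monitor`` (if requested) ignores the component count and
    produces a single result with k = 0.
    """
    y = monitor_set.conc_sqrt
    n = len(monitor_set)
    X = monitor_design(monitor_set, covariates)
    folds = assign_folds(n, n_folds=n_folds, seed=seed)
    k_grid = [int(k) for k in k_grid]

    candidates = []
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        candidates += [(method, 0)] if method == "nearest_monitor" \
            else [(method, k) for k in k_grid]

    preds = {c: np.full(n, np.nan) for c in candidates}
    for fold in range(1, n_folds + 1):
        test = folds == fold
        train = ~test
        X_tr, y_tr = X.loc[train].reset_index(drop=True), y[train]
        X_te = X.loc[test].reset_index(drop=True)
        for method, k in candidates:
            model = ExposureModel(n_components=max(k, 1), family=family,
                                  method=method, preprocessor=preprocessor)
            model.fit(X_tr, y_tr)
            preds[(method, k)][test] = model.predict(X_te)

    results = []
    for (method, k), p in preds.items():
        results.append(CVResult(method=method, k=k, fold_assignment=folds,
                                cv_predictions=p, rmsep=rmsep(y, p),
                                r2=cv_r2(y, p)))
    return results


_METHOD_ORDER = {"pls_only": 0, "pls_uk": 1, "nearest_monitor": 2}


def select_model(cv_results) -> tuple[str, int]:
    """(method, k) minimizing RMSEP; ties → smaller k, then pls_only first."""
    if not cv_results:
        raise ValueError("no CV results to select from")
    best = min(cv_results,
               key=lambda r: (r.rmsep, r.k, _METHOD_ORDER.get(r.method, 99)))
    return best.method, best.k


def cv_table(cv_results) -> pd.DataFrame:
    return pd.DataFrame([{"method": r.method, "k": r.k,
                          "rmsep": r.rmsep, "r2": r.r2}
                         for r in cv_results])
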