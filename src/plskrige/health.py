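"""Stage-two disease model: OLS with naive (model-based) inference.

E(Y) = β₀ + W β_x + Z β_z with W the exposure on the untransformed scale.
Confidence intervals use the normal approximation with z = 1.96 at the 95%
level (matching the printed-interval convention of large-cohort analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class HealthFit:
    """OLS fit of the disease model with naive SEs and normal CIs."""

    beta0: float
    beta_x: float
    beta_z: np.ndarray
    se: dict                       # term -> naive SE
    ci: dict                       # term -> (lower, upper)
    level: float
    n_used: int
    n_dropped: int
    sigma_resid: float
    terms: list

    def coefficient_table(self, method: str = "naive") -> pd.DataFrame:
        rows = []
        est = {"intercept": self.beta0, "exposure": self.beta_x}
        for i, t in enumerate(self.terms[2:]):
            est[t] = self.beta_z[i]
        for term in self.terms:
            lo, hi = self.ci[term]
            rows.append({"term": term, "estimate": est[term],
                         "se": self.se[term], "ci_lo": lo, "ci_hi": hi,
                         "method": method})
        return pd.DataFrame(rows)


def normal_ci(estimate: float, se: float, level: float = 0.95):
    """estimate ± z·se; z = 1.96 exactly at the 95% level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("se must be non-negative")
    z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 * (1 + level)))
    return estimate - z * se, estimate + z * se


def fit_health_ols(Y, W, Z=None, level: float = 0.95,
                   z_names=None) -> HealthFit:
    """Complete-case OLS of the outcome on exposure and adjustment covariates."""
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0):
        Z = np.empty((Y.shape[0], 0))
        z_cols = []
    else:
        if isinstance(Z, pd.DataFrame):
            z_cols = list(Z.columns)
            Z = Z.to_numpy(dtype=float)
        else:
            Z = np.asarray(Z, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            z_cols = z_names or [f"z_{j + 1}" for j in range(Z.shape[1])]
    if W.shape[0] != Y.shape[0] or Z.shape[0] != Y.shape[0]:
        raise ValueError("Y, W, Z are not row-aligned")

    design = np.column_stack([np.ones_like(Y), W, Z])
    terms = ["intercept", "exposure"] + z_cols
    complete = np.all(np.isfinite(np.column_stack([Y[:, None], design])), axis=1)
    n_dropped = int(np.sum(~complete))
    if n_dropped:
        logger.info("dropped %d incomplete cases", n_dropped)
    Yc, Dc = Y[complete], design[complete]

    rank = np.linalg.matrix_rank(Dc)
    if rank < Dc.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(Dc, pivoting=True, mode="economic")
        bad = sorted(piv[rank:].tolist())
        names = [terms[i] for i in bad]
        raise ValueError(f"rank-deficient design; collinear columns: {names}")

    res = sm.OLS(Yc, Dc).fit()
    params = res.params
    ses = res.bse
    nz = len(z_cols)
    se = {t: float(ses[i]) for i, t in enumerate(terms)}
    ci = {t: normal_ci(float(params[i]), float(ses[i]), level)
          for i, t in enumerate(terms)}
    return HealthFit(beta0=float(params[0]), beta_x=float(params[1]),
                     beta_z=np.asarray(params[2:], dtype=float),
                     se=se, ci=ci, level=level, n_used=int(complete.sum()),
                     n_dropped=n_dropped,
                     sigma_resid=float(np.sqrt(res.mse_resid)),
                     terms=terms)
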