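"""Semivariogram / correlation families for the spatial residual field.

Three isotropic families are supported. With nugget τ², partial sill σ² and
range φ the semivariogram is

    γ(d) = τ² + σ² (1 − ρ(d/φ))   for d > 0,     γ(0) = 0,

where ρ is the family correlation function:

* exponential: ρ(h) = exp(−h) (sill approached asymptotically);
* spherical:   ρ(h) = 1 − 1.5 h + 0.5 h³ for h ≤ 1, 0 beyond (sill at d = φ);
* cubic:       ρ(h) = 1 − (7h² − 8.75h³ + 3.5h⁵ − 0.75h⁷) for h ≤ 1, 0 beyond.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

FAMILIES = ("exponential", "spherical", "cubic")


def correlation(family: str, d: np.ndarray, phi: float) -> np.ndarray:
    """Spatial correlation ρ(d/φ) for a variogram family."""
    if phi <= 0:
        raise ValueError("range phi must be positive")
    d = np.asarray(d, dtype=float)
    h = d / phi
    if family == "exponential":
        return np.exp(-h)
    if family == "spherical":
        h = np.minimum(h, 1.0)
        return 1.0 - 1.5 * h + 0.5 * h ** 3
    if family == "cubic":
        h = np.minimum(h, 1.0)
        return 1.0 - (7 * h ** 2 - 8.75 * h ** 3 + 3.5 * h ** 5 - 0.75 * h ** 7)
    raise ValueError(f"unknown variogram family: {family!r}")


def semivariogram(family: str, theta, d) -> np.ndarray:
    """γ(d) for θ = (τ², σ², φ). γ(0) = 0 exactly; lim_{d→0⁺} γ = τ²."""
    tau2, sigma2, phi = theta
    if tau2 < 0 or sigma2 < 0:
        raise ValueError("nugget and partial sill must be non-negative")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    gamma = tau2 + sigma2 * (1.0 - correlation(family, d, phi))
    return np.where(d == 0, 0.0, gamma)


def covariance_matrix(theta, dist_matrix: np.ndarray, family: str) -> np.ndarray:
    """Σ(θ) = τ² I + σ² ρ(D/φ) for a square distance matrix D."""
    tau2, sigma2, phi = theta
    sigma = sigma2 * correlation(family, dist_matrix, phi)
    sigma[np.diag_indices_from(sigma)] += tau2
    return sigma


def cross_covariance(theta, coords_new, coords_obs, family: str) -> np.ndarray:
    """Cross-covariance σ² ρ(d/φ) between prediction and observation sites.

    No nugget term for distinct sites; a prediction site coincident with an
    observation site gets covariance σ² (the nugget is treated as
    site-specific noise, so exact interpolation holds only when τ² = 0).
    """
    d = cdist(np.asarray(coords_new, float), np.asarray(coords_obs, float))
    tau2, sigma2, phi = theta
    return sigma2 * correlation(family, d, phi)


def empirical_semivariogram(coords, values, n_bins: int = 15,
                            max_dist: float | None = None):
    """Binned method-of-moments semivariogram of ``values`` at ``coords``.

    Returns (bin centers, semivariances, pair counts). Used to seed the
    likelihood optimisation and for diagnostics.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    dists = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    sqdiff = sq[iu]
    if max_dist is None:
        max_dist = np.max(dists) / 2.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dists > lo) & (dists <= hi)
        if not np.any(mask):
            continue
        centers.append(0.5 * (lo + hi))
        gammas.append(float(np.mean(sqdiff[mask])))
        counts.append(int(np.sum(mask)))
    return np.array(centers), np.array(gammas), np.array(counts)
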