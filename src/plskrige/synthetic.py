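"""Synthetic study generator with known ground truth.

Emulates the data structure of a national two-stage air-pollution study:
quasi-uniform monitoring sites and urban-clustered subjects on a projected
plane, geographic covariates carrying a low-rank smooth spatial signal,
sqrt-scale exposures drawn jointly at all sites from a Gaussian process with
mean linear in the latent covariate factors and covariance
τ² I + σ² ρ(d/φ), and health outcomes linear in the untransformed exposure.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .containers import MonitorSet
from .variogram import FAMILIES, covariance_matrix

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Ground-truth parameters for a synthetic two-stage study.

    ``theta_true`` = (nugget τ², partial sill σ², range φ in km) governs the
    spatial residual field on the sqrt-concentration scale; ``alpha_true`` is
    (intercept, per-latent-factor slope) of the exposure mean;
    ``beta_true`` = (β₀, β_x, β_z...) are the health-model coefficients with
    β_x acting on the untransformed exposure scale.
    """

    n_monitors: int = 288
    n_subjects: int = 500
    region_size: float = 4000.0          # km, square side
    cluster_fraction: float = 0.9
    n_clusters: int = 6
    cluster_sd: float = 30.0             # km
    p_covariates: int = 50
    n_latent: int = 2
    n_distance: int = 5                  # distance-like (positive, heavy-tailed) columns
    covariate_noise_sd: float = 0.5
    alpha_true: tuple = (0.70, 0.10, 0.05)
    theta_true: tuple = (0.0007, 0.0251, 2145.0)
    variogram_family: str = "exponential"
    beta_true: tuple = (0.68, 0.055, 0.02)
    sigma_y: float = 0.19
    misspecified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        tau2, sigma2, phi = self.theta_true
        if tau2 < 0 or sigma2 < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if phi <= 0:
            raise ValueError("range must be positive")
        if self.region_size <= 0:
            raise ValueError("region_size must be positive")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.n_latent > self.p_covariates - self.n_distance:
            raise ValueError("n_latent exceeds number of signal covariates")
        for name in ("n_monitors", "n_subjects", "n_clusters",
                     "p_covariates", "n_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_distance < 0 or self.n_distance >= self.p_covariates:
            raise ValueError("n_distance must be in [0, p_covariates)")
        if len(self.alpha_true) != self.n_latent + 1:
            raise ValueError("alpha_true must have length n_latent + 1")
        if len(self.beta_true) < 2:
            raise ValueError("beta_true needs at least (beta0, beta_x)")
        if self.variogram_family not in FAMILIES:
            raise ValueError(f"unknown family {self.variogram_family!r}")

    # Preset scenarios with variogram regimes mirroring strongly and weakly
    # spatial pollutants (sulfur-like vs elemental-carbon-like).
    @classmethod
    def s_like(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("theta_true", (0.0007, 0.0251, 2145.0))
        return cls(**kw)

    @classmethod
    def ec_like(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("theta_true", (0.0074, 0.0025, 413.0))
        return cls(**kw)

    @classmethod
    def no_spatial(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("theta_true", (0.0099, 0.0, 500.0))
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_true"] = list(self.alpha_true)
        d["theta_true"] = list(self.theta_true)
        d["beta_true"] = list(self.beta_true)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("alpha_true", "theta_true", "beta_true"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticStudy:
    """A generated study: geometry, covariates, truth, and outcomes."""

    config: ScenarioConfig
    monitor_set: MonitorSet
    subject_ids: np.ndarray
    subject_coords: np.ndarray
    covariates_monitors: pd.DataFrame
    covariates_subjects: pd.DataFrame
    latent_monitors: np.ndarray
    latent_subjects: np.ndarray
    true_exposure_subjects: np.ndarray   # sqrt scale
    health_outcomes: np.ndarray
    adjustment_covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        aligned = (self.subject_coords.shape[0] == n
                   and len(self.covariates_subjects) == n
                   and self.true_exposure_subjects.shape[0] == n
                   and self.health_outcomes.shape[0] == n
                   and len(self.adjustment_covariates) == n)
        if not aligned:
            raise ValueError("subject tables are not row-aligned")
        if len(self.covariates_monitors) != len(self.monitor_set):
            raise ValueError("monitor tables are not row-aligned")

    def write_csvs(self, outdir) -> dict:
        """Write monitors.csv, covariates.csv, subjects.csv + config.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.17g"
        paths = {}
        mon = self.monitor_set.to_frame()
        paths["monitors"] = outdir / "monitors.csv"
        mon.to_csv(paths["monitors"], index=False, float_format=fmt)

        cov_m = self.covariates_monitors.copy()
        cov_m.insert(0, "id", self.monitor_set.ids)
        cov_s = self.covariates_subjects.copy()
        cov_s.insert(0, "id", self.subject_ids)
        paths["covariates"] = outdir / "covariates.csv"
        pd.concat([cov_m, cov_s], ignore_index=True).to_csv(
            paths["covariates"], index=False, float_format=fmt)

        sub = pd.DataFrame({
            "id": self.subject_ids,
            "x": self.subject_coords[:, 0],
            "y": self.subject_coords[:, 1],
            "y_outcome": self.health_outcomes,
        })
        for j, col in enumerate(self.adjustment_covariates.columns):
            sub[col] = self.adjustment_covariates[col].to_numpy()
        paths["subjects"] = outdir / "subjects.csv"
        sub.to_csv(paths["subjects"], index=False, float_format=fmt)

        paths["config"] = outdir / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=False)
        return paths


def generate_locations(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Quasi-uniform monitor grid (jittered) + urban-clustered subjects."""
    if cfg.region_size <= 0:
        raise ValueError("region_size must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    L = cfg.region_size

    # monitors: stratified jittered grid, evenly dispersed over the region
    side = int(np.ceil(np.sqrt(cfg.n_monitors)))
    cell = L / side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    cells = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    take = rng.permutation(len(cells))[:cfg.n_monitors]
    monitors = (cells[take] + rng.uniform(0, 1, size=(cfg.n_monitors, 2))) * cell

    # subjects: a fraction in tight urban clusters, remainder uniform
    centers = rng.uniform(0.15 * L, 0.85 * L, size=(cfg.n_clusters, 2))
    n_clustered = int(round(cfg.cluster_fraction * cfg.n_subjects))
    which = rng.integers(0, cfg.n_clusters, size=n_clustered)
    clustered = centers[which] + rng.normal(0, cfg.cluster_sd, size=(n_clustered, 2))
    uniform = rng.uniform(0, L, size=(cfg.n_subjects - n_clustered, 2))
    subjects = np.clip(np.vstack([clustered, uniform]), 0.0, L)
    return monitors, subjects


def _smooth_factors(coords: np.ndarray, n_latent: int, region_size: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth spatial factor fields (sums of low-frequency waves)."""
    n = coords.shape[0]
    F = np.empty((n, n_latent))
    n_waves = 4
    for l in range(n_latent):
        wavelengths = rng.uniform(region_size / 3.0, region_size, size=n_waves)
        angles = rng.uniform(0, 2 * np.pi, size=n_waves)
        phases = rng.uniform(0, 2 * np.pi, size=n_waves)
        amps = rng.normal(size=n_waves)
        vals = np.zeros(n)
        for w in range(n_waves):
            proj = coords[:, 0] * np.cos(angles[w]) + coords[:, 1] * np.sin(angles[w])
            vals += amps[w] * np.cos(2 * np.pi * proj / wavelengths[w] + phases[w])
        sd = vals.std()
        F[:, l] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return F


def generate_covariates(coords, cfg: ScenarioConfig,
                        rng: np.random.Generator | None = None):
    """Covariate table = latent smooth factors × loadings + noise.

    Returns (table, latent factors). The first ``p - n_distance`` columns
    (``cov_*``) carry the low-rank signal PLS assumes; the remaining
    ``dist_*`` columns are positive, heavy-tailed distance-like variables
    used by the preprocessing stage.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate list")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = coords.shape[0]
    p_signal = cfg.p_covariates - cfg.n_distance

    F = _smooth_factors(coords, cfg.n_latent, cfg.region_size, rng)
    loadings = rng.normal(size=(p_signal, cfg.n_latent))
    table = F @ loadings.T
    if cfg.misspecified:
        # nonlinear contamination violating the linear-in-factors assumption
        table = table + 0.3 * (F[:, [0]] ** 2 - 1.0)
    if cfg.covariate_noise_sd > 0:
        table = table + cfg.covariate_noise_sd * rng.normal(size=(n, p_signal))
    cols = {f"cov_{j + 1}": table[:, j] for j in range(p_signal)}
    # distance-like covariates: km to nearest feature, lognormal
    dists = rng.lognormal(mean=np.log(2.0), sigma=0.75,
                          size=(n, cfg.n_distance))
    for j in range(cfg.n_distance):
        cols[f"dist_{j + 1}"] = dists[:, j]
    return pd.DataFrame(cols), F


def generate_true_surface(coords_all, scores_all, cfg: ScenarioConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """One joint sqrt-scale exposure draw at all sites (monitors + subjects).

    mean = α₀ + scores·α₁ and residual η ~ N(0, τ² I + σ² ρ(d/φ)).
    """
    coords_all = np.asarray(coords_all, dtype=float)
    scores_all = np.asarray(scores_all, dtype=float)
    if scores_all.shape[0] != coords_all.shape[0]:
        raise ValueError("scores not row-aligned with coords")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    alpha = np.asarray(cfg.alpha_true, dtype=float)
    mean = alpha[0] + scores_all @ alpha[1:]
    tau2, sigma2, phi = cfg.theta_true
    if tau2 == 0 and sigma2 == 0:
        return mean.copy()
    D = cdist(coords_all, coords_all)
    cov = covariance_matrix(cfg.theta_true, D, cfg.variogram_family)
    L = _chol_with_jitter(cov)
    return mean + L @ rng.standard_normal(coords_all.shape[0])


def _chol_with_jitter(cov: np.ndarray, base: float = 1e-10,
                      tries: int = 4) -> np.ndarray:
    scale = np.mean(np.diag(cov)) or 1.0
    jitter = 0.0
    for t in range(tries):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter = base * scale * 10 ** t
    raise np.linalg.LinAlgError(
        "covariance not positive definite even after jitter")


def generate_health(true_exposure_sqrt, Z, cfg: ScenarioConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Y = β₀ + W β_x + Z β_z + ε with W the squared sqrt-scale exposure."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    x = np.asarray(true_exposure_sqrt, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    beta = np.asarray(cfg.beta_true, dtype=float)
    beta_z = beta[2:]
    if Z.shape[0] != x.shape[0]:
        raise ValueError("true exposures and Z are not row-aligned")
    if Z.shape[1] != beta_z.shape[0]:
        raise ValueError("Z has wrong number of columns for beta_z")
    W = x ** 2
    y = beta[0] + W * beta[1] + Z @ beta_z
    if cfg.sigma_y > 0:
        y = y + cfg.sigma_y * rng.standard_normal(x.shape[0])
    return y


def generate_study(cfg: ScenarioConfig) -> SyntheticStudy:
    """Generate a full synthetic study; deterministic given ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    r_loc, r_cov, r_surf, r_health = (np.random.default_rng(s)
                                      for s in ss.spawn(4))
    mon_coords, sub_coords = generate_locations(cfg, r_loc)
    coords_all = np.vstack([mon_coords, sub_coords])
    cov_all, latent_all = generate_covariates(coords_all, cfg, r_cov)
    x_all = generate_true_surface(coords_all, latent_all, cfg, r_surf)

    nm = cfg.n_monitors
    x_mon, x_sub = x_all[:nm], x_all[nm:]
    n_neg = int(np.sum(x_mon < 0))
    if n_neg:
        logger.warning("floored %d negative sqrt-scale monitor values", n_neg)
        x_mon = np.clip(x_mon, 0.0, None)

    q = len(cfg.beta_true) - 2
    Z = r_health.standard_normal((cfg.n_subjects, q)) if q else np.empty((cfg.n_subjects, 0))
    y = generate_health(x_sub, Z, cfg, r_health)

    monitor_set = MonitorSet(ids=np.arange(1, nm + 1),
                             coords=mon_coords,
                             conc_raw=x_mon ** 2,
                             conc_sqrt=x_mon)
    return SyntheticStudy(
        config=cfg,
        monitor_set=monitor_set,
        subject_ids=np.arange(nm + 1, nm + cfg.n_subjects + 1),
        subject_coords=sub_coords,
        covariates_monitors=cov_all.iloc[:nm].reset_index(drop=True),
        covariates_subjects=cov_all.iloc[nm:].reset_index(drop=True),
        latent_monitors=latent_all[:nm],
        latent_subjects=latent_all[nm:],
        true_exposure_subjects=x_sub,
        health_outcomes=y,
        adjustment_covariates=pd.DataFrame(
            {f"z_{j + 1}": Z[:, j] for j in range(q)}),
    )
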