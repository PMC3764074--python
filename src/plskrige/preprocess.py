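"""Geographic-covariate preprocessing preceding PLS.

Fixed pipeline order: homogeneity screen → outlier screen → distance
compile/log-truncate → re-screen compiled columns → mean-center and scale.
Screening decisions and standardization statistics are learned on the
monitor table and applied unchanged to subject tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

# 1 m floor applied to distances before the log transform
DEFAULT_DISTANCE_FLOOR_KM = 0.001


@dataclass
class PrepReport:
    """Provenance of a preprocessing fit: what was dropped/derived and why."""

    dropped_homogeneous: list = field(default_factory=list)
    dropped_outlier: list = field(default_factory=list)
    transformed_distance: list = field(default_factory=list)
    compiled: list = field(default_factory=list)
    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    log_base: str = "e"
    distance_cap: float = 10.0

    def __post_init__(self) -> None:
        overlap = set(self.dropped_homogeneous) & set(self.dropped_outlier)
        if overlap:
            raise ValueError(f"columns dropped twice: {sorted(overlap)}")
        if set(self.centers) != set(self.scales):
            raise ValueError("centers/scales keys differ")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("scales must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def drop_homogeneous(table: pd.DataFrame, threshold: float = 0.85):
    """Drop columns whose modal value occurs in strictly more than
    ``threshold`` of rows. Returns (table, dropped names)."""
    if table.shape[1] == 0:
        raise ValueError("empty covariate table")
    n = len(table)
    dropped = []
    for col in table.columns:
        top = table[col].value_counts(dropna=False).iloc[0]
        if top > threshold * n:
            dropped.append(col)
    return table.drop(columns=dropped), dropped


def drop_outlier_prone(table: pd.DataFrame, cutoff: float = 7.0):
    """Drop columns whose most extreme standardized value exceeds ``cutoff``."""
    dropped = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            continue  # constant columns are the homogeneity screen's job
        if np.max(np.abs((x - x.mean()) / sd)) > cutoff:
            dropped.append(col)
    return table.drop(columns=dropped), dropped


def transform_distances(table: pd.DataFrame, distance_columns,
                        cap: float = 10.0, log_base: str = "e",
                        floor: float = DEFAULT_DISTANCE_FLOOR_KM) -> pd.DataFrame:
    """Replace each distance d by log(min(max(d, floor), cap)).

    ``cap`` defaults to 10 km; ``log_base`` is "e" or "10".
    """
    log = np.log if log_base == "e" else np.log10
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    out = table.copy()
    for col in distance_columns:
        if col not in out.columns:
            continue
        d = out[col].to_numpy(dtype=float)
        if np.any(d < 0):
            raise ValueError(f"negative distances in column {col!r}")
        d = np.maximum(d, floor)
        if np.any(d <= 0):
            raise ValueError(f"non-positive distance after flooring in {col!r}")
        out[col] = log(np.minimum(d, cap))
    return out


def compile_min_distances(table: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Add per-group row-wise minima over raw (pre-log) member distances.

    ``groups`` maps a new column name to a list of member column names.
    """
    out = table.copy()
    for name, members in groups.items():
        if not members:
            raise ValueError(f"empty compile group {name!r}")
        missing = [m for m in members if m not in table.columns]
        if missing:
            raise ValueError(f"group {name!r} references missing columns {missing}")
        out[name] = table[list(members)].min(axis=1)
    return out


def standardize(table: pd.DataFrame):
    """Mean-center and scale by sample SD. Returns (table, centers, scales)."""
    centers = table.mean()
    scales = table.std(ddof=1)
    zero = scales[scales == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-SD columns cannot be standardized: {zero}")
    return (table - centers) / scales, centers, scales


class CovariatePreprocessor(BaseEstimator, TransformerMixin):
    """Screens, transforms and standardizes a geographic-covariate table.

    Parameters
    ----------
    homogeneity_threshold : float, default 0.85
        Drop columns whose modal value covers strictly more than this
        proportion of rows.
    outlier_cutoff : float, default 7.0
        Drop columns with a standardized value beyond this magnitude.
    distance_cap : float, default 10.0
        Truncation (km) applied to distance columns before the log.
        (25 km paired with base-10 log is the common alternative convention.)
    log_base : {"e", "10"}, default "e"
    distance_columns : list of str or None
        Distance-type columns; ``None`` selects columns starting with "dist".
    compile_groups : dict or None
        Extra "minimum distance to any member" columns to derive, screened
        with the same inclusion criteria as original covariates.
    """

    def __init__(self, homogeneity_threshold: float = 0.85,
                 outlier_cutoff: float = 7.0, distance_cap: float = 10.0,
                 log_base: str = "e", distance_columns=None,
                 compile_groups=None,
                 distance_floor: float = DEFAULT_DISTANCE_FLOOR_KM):
        self.homogeneity_threshold = homogeneity_threshold
        self.outlier_cutoff = outlier_cutoff
        self.distance_cap = distance_cap
        self.log_base = log_base
        self.distance_columns = distance_columns
        self.compile_groups = compile_groups
        self.distance_floor = distance_floor

    def _dist_cols(self, table: pd.DataFrame) -> list:
        if self.distance_columns is not None:
            return [c for c in self.distance_columns if c in table.columns]
        return [c for c in table.columns if str(c).startswith("dist")]

    def fit(self, X: pd.DataFrame, y=None) -> "CovariatePreprocessor":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        table, dropped_h = drop_homogeneous(X, self.homogeneity_threshold)
        table, dropped_o = drop_outlier_prone(table, self.outlier_cutoff)

        groups = dict(self.compile_groups or {})
        # groups whose members were screened out are dropped silently only if
        # empty; surviving members suffice
        live_groups = {}
        for name, members in groups.items():
            alive = [m for m in members if m in table.columns]
            if not alive:
                raise ValueError(f"compile group {name!r} has no surviving members")
            live_groups[name] = alive
        compiled_names = list(live_groups)
        table = compile_min_distances(table, live_groups)

        dist_cols = self._dist_cols(X)
        dist_like = [c for c in table.columns
                     if c in dist_cols or c in compiled_names]
        table = transform_distances(table, dist_like, cap=self.distance_cap,
                                    log_base=self.log_base,
                                    floor=self.distance_floor)

        # compiled columns face the same inclusion criteria as originals
        comp_tab = table[compiled_names]
        if compiled_names:
            comp_tab, ch = drop_homogeneous(comp_tab, self.homogeneity_threshold)
            comp_tab, co = drop_outlier_prone(comp_tab, self.outlier_cutoff)
            dropped_h += ch
            dropped_o += co
            table = table.drop(columns=[c for c in compiled_names
                                        if c not in comp_tab.columns])

        table, centers, scales = standardize(table)
        self.columns_in_ = list(X.columns)
        self.columns_out_ = list(table.columns)
        self.dist_like_ = [c for c in dist_like if c in table.columns]
        self.groups_ = {k: v for k, v in live_groups.items()
                        if k in table.columns}
        self.centers_ = centers
        self.scales_ = scales
        self.report_ = PrepReport(
            dropped_homogeneous=dropped_h,
            dropped_outlier=dropped_o,
            transformed_distance=list(dist_like),
            compiled=compiled_names,
            centers=centers.to_dict(),
            scales=scales.to_dict(),
            log_base=self.log_base,
            distance_cap=self.distance_cap,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "columns_out_"):
            raise RuntimeError("preprocessor is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=self.columns_in_)
        missing = [c for c in self.columns_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        table = compile_min_distances(X, self.groups_)
        table = transform_distances(table, self.dist_like_,
                                    cap=self.distance_cap,
                                    log_base=self.log_base,
                                    floor=self.distance_floor)
        table = table[self.columns_out_]
        return (table - self.centers_) / self.scales_
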