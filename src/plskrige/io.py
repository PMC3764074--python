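"""CSV readers/writers and run configuration for the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MonitorSet

FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            raise ValueError(f"{path}: non-numeric values in column {c!r}")
        df[c] = converted
    return df


def read_monitors(path) -> MonitorSet:
    """Read monitors.csv (id, x, y, conc_raw [or conc_sqrt]).

    Raw concentrations are square-root transformed on load.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["id", "x", "y"], path)
    if "conc_raw" in df.columns:
        df = _numeric(df, ["x", "y", "conc_raw"], path)
        if (df["conc_raw"] < 0).any():
            raise ValueError(f"{path}: negative concentrations")
        conc_raw = df["conc_raw"].to_numpy(dtype=float)
    elif "conc_sqrt" in df.columns:
        df = _numeric(df, ["x", "y", "conc_sqrt"], path)
        if (df["conc_sqrt"] < 0).any():
            raise ValueError(f"{path}: negative sqrt-scale concentrations")
        conc_raw = df["conc_sqrt"].to_numpy(dtype=float) ** 2
    else:
        raise ValueError(f"{path}: need a conc_raw or conc_sqrt column")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate monitor ids")
    return MonitorSet(ids=df["id"].to_numpy(),
                      coords=df[["x", "y"]].to_numpy(dtype=float),
                      conc_raw=conc_raw)


def read_covariates(path) -> pd.DataFrame:
    """Covariate table indexed by location id (all remaining columns numeric)."""
    df = pd.read_csv(path)
    _require_columns(df, ["id"], path)
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate location ids")
    value_cols = [c for c in df.columns if c != "id"]
    if not value_cols:
        raise ValueError(f"{path}: no covariate columns")
    df = _numeric(df, value_cols, path)
    return df.set_index("id")


def read_subjects(path) -> pd.DataFrame:
    """Subjects table: id, x, y, y_outcome, z_* adjustment covariates."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "x", "y", "y_outcome"], path)
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    value_cols = [c for c in df.columns if c != "id"]
    return _numeric(df, value_cols, path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


@dataclass
class RunConfig:
    """All options of an end-to-end pipeline run."""

    monitors_csv: str
    covariates_csv: str
    subjects_csv: str
    output_dir: str
    # preprocessing
    distance_cap: float = 10.0
    log_base: str = "e"
    # exposure model
    family: str = "exponential"
    k_grid: tuple = (1, 2, 3)
    n_folds: int = 10
    cv_methods: tuple = ("pls_only", "pls_uk")
    # bootstrap
    bootstrap_B: int = 1000
    bootstrap_lambda: float = 1.0
    run_simex: bool = False
    lambda_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.monitors_csv, self.covariates_csv, self.subjects_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")
        if self.n_folds < 2 or self.bootstrap_B < 2:
            raise ValueError("n_folds and bootstrap_B must be >= 2")
        if self.bootstrap_lambda < 0:
            raise ValueError("bootstrap lambda must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("k_grid", "cv_methods", "lambda_grid"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("k_grid", "cv_methods", "lambda_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # analysis options only
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
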