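"""Core data containers shared across the two-stage pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MonitorSet:
    """Monitoring locations with observed annual-average concentrations.

    Concentrations are stored on both the raw scale (``conc_raw``, e.g. μg/m³)
    and the square-root scale (``conc_sqrt``) used for all spatial modelling.

    Parameters
    ----------
    ids : array-like
        Unique monitor identifiers.
    coords : ndarray of shape (n, 2)
        Projected planar coordinates in km.
    conc_raw : ndarray of shape (n,)
        Non-negative raw-scale concentrations.
    conc_sqrt : ndarray of shape (n,), optional
        Square-root-scale concentrations; computed from ``conc_raw`` when
        omitted, validated for consistency when given.
    """

    ids: np.ndarray
    coords: np.ndarray
    conc_raw: np.ndarray
    conc_sqrt: np.ndarray = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.coords = np.asarray(self.coords, dtype=float)
        self.conc_raw = np.asarray(self.conc_raw, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        n = len(self.ids)
        if self.coords.shape[0] != n or self.conc_raw.shape[0] != n:
            raise ValueError("ids, coords and concentrations must be row-aligned")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate monitor ids")
        if np.min(self.conc_raw) < 0:
            raise ValueError("negative raw concentrations")
        if self.conc_sqrt is None:
            self.conc_sqrt = np.sqrt(self.conc_raw)
        else:
            self.conc_sqrt = np.asarray(self.conc_sqrt, dtype=float)
            if self.conc_sqrt.shape[0] != n:
                raise ValueError("conc_sqrt misaligned")
            if not np.allclose(self.conc_sqrt, np.sqrt(self.conc_raw),
                               rtol=1e-9, atol=1e-12):
                raise ValueError("conc_sqrt inconsistent with sqrt(conc_raw)")
        # duplicate coordinates make the kriging covariance singular
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("duplicate monitor coordinates are not supported")

    @classmethod
    def from_raw(cls, ids, coords, conc_raw) -> "MonitorSet":
        return cls(ids=ids, coords=coords, conc_raw=conc_raw)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "conc_raw": self.conc_raw,
            "conc_sqrt": self.conc_sqrt,
        })


@dataclass
class ExposurePredictions:
    """Exposure predictions on the sqrt and untransformed scales.

    ``pred_raw`` equals ``pred_sqrt`` squared elementwise, after flooring
    negative sqrt-scale predictions at zero (count kept in ``n_floored``).
    """

    ids: np.ndarray
    pred_sqrt: np.ndarray
    pred_raw: np.ndarray
    method: str
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.pred_sqrt = np.asarray(self.pred_sqrt, dtype=float)
        self.pred_raw = np.asarray(self.pred_raw, dtype=float)
        if not np.all(np.isfinite(self.pred_sqrt)):
            raise ValueError("non-finite sqrt-scale predictions")
        if not np.all(np.isfinite(self.pred_raw)):
            raise ValueError("non-finite raw-scale predictions")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "pred_sqrt": self.pred_sqrt,
            "pred_raw": self.pred_raw,
            "method": self.method,
        })


def floored_square(pred_sqrt: np.ndarray) -> tuple[np.ndarray, int]:
    """Back-transform sqrt-scale predictions, flooring negatives at zero."""
    pred_sqrt = np.asarray(pred_sqrt, dtype=float)
    n_floored = int(np.sum(pred_sqrt < 0))
    return np.clip(pred_sqrt, 0.0, None) ** 2, n_floored
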