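"""Long-format panel containers and latent-trajectory containers.

``PanelData`` wraps a pandas DataFrame with columns

    id, time, y1..yp, x1..xr, z1..zs [, R_* indicator columns]

sorted by (id, time), with consecutive integer time indices within person and
NaN as the in-memory missing sentinel (written as "NA" on disk).  Auxiliary
``z`` columns must be fully observed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PanelData", "LatentPaths", "read_panel_csv", "write_panel_csv"]


def _numbered(columns, prefix):
    pat = re.compile(rf"^{prefix}(\d+)$")
    hits = sorted((int(m.group(1)), c) for c in columns if (m := pat.match(c)))
    cols = [c for _, c in hits]
    if [i for i, _ in hits] != list(range(1, len(cols) + 1)):
        raise ValueError(f"{prefix}* columns must be numbered consecutively from 1")
    return cols


class PanelData:
    """Person x time panel of manifest variables, covariates and auxiliaries."""

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy()
        if "id" not in frame.columns or "time" not in frame.columns:
            raise ValueError("panel frame needs 'id' and 'time' columns")
        frame["id"] = frame["id"].astype(int)
        frame["time"] = frame["time"].astype(int)
        self.y_cols = _numbered(frame.columns, "y")
        self.x_cols = _numbered(frame.columns, "x")
        self.z_cols = _numbered(frame.columns, "z")
        self.indicator_cols = [c for c in frame.columns if c.startswith("R_")]
        known = {"id", "time", *self.y_cols, *self.x_cols, *self.z_cols,
                 *self.indicator_cols}
        unknown = [c for c in frame.columns if c not in known]
        if unknown:
            raise ValueError(f"unknown panel columns: {unknown}")
        order = ["id", "time", *self.y_cols, *self.x_cols, *self.z_cols,
                 *self.indicator_cols]
        frame = frame[order].sort_values(["id", "time"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        for c in self.y_cols + self.x_cols + self.z_cols + self.indicator_cols:
            frame[c] = frame[c].astype(float)
        self.frame = frame
        if validate:
            self._validate()

    def _validate(self):
        bad = []
        for pid, g in self.frame.groupby("id"):
            t = g["time"].to_numpy()
            if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
                bad.append(int(pid))
        if bad:
            raise ValueError(f"non-consecutive time indices for persons {bad}")
        if self.z_cols and self.frame[self.z_cols].isna().any().any():
            raise ValueError("auxiliary z columns must be fully observed")

    # -- shape ----------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.y_cols)

    @property
    def r(self) -> int:
        return len(self.x_cols)

    @property
    def s(self) -> int:
        return len(self.z_cols)

    @property
    def n_persons(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def person_ids(self) -> np.ndarray:
        return self.frame["id"].unique()

    def person_starts(self) -> np.ndarray:
        """Row offsets of each person block, length n_persons + 1."""
        counts = self.frame.groupby("id", sort=False).size().to_numpy()
        return np.concatenate([[0], np.cumsum(counts)])

    # -- arrays ---------------------------------------------------------
    @property
    def y(self) -> np.ndarray:
        return self.frame[self.y_cols].to_numpy()

    @property
    def x(self) -> np.ndarray:
        return self.frame[self.x_cols].to_numpy() if self.x_cols else np.zeros((self.n_rows, 0))

    @property
    def z(self) -> np.ndarray:
        return self.frame[self.z_cols].to_numpy() if self.z_cols else np.zeros((self.n_rows, 0))

    @property
    def mask(self) -> pd.DataFrame:
        """Missingness mask over y and x columns (True = missing)."""
        return self.frame[self.y_cols + self.x_cols].isna()

    def copy(self) -> "PanelData":
        return PanelData(self.frame.copy(), validate=False)

    def equals(self, other: "PanelData") -> bool:
        return self.frame.equals(other.frame)

    def __repr__(self):
        return (f"PanelData(n_persons={self.n_persons}, rows={self.n_rows}, "
                f"p={self.p}, r={self.r}, s={self.s})")

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_panel_csv(self, path)

    @classmethod
    def from_csv(cls, path) -> "PanelData":
        return read_panel_csv(path)


def write_panel_csv(panel: PanelData, path) -> None:
    # default float repr round-trips exactly: read(write(p)) == p
    panel.frame.to_csv(path, index=False, na_rep="NA")


def read_panel_csv(path) -> PanelData:
    frame = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False,
                        comment="#", float_precision="round_trip")
    return PanelData(frame)


@dataclass
class LatentPaths:
    """True or estimated latent-state trajectories with per-occasion covariance.

    ``states`` is a DataFrame (id, time, f1..fq); ``covs`` is an
    (n_rows, q, q) array aligned with its rows; ``kind`` is one of
    'true', 'filtered', 'smoothed' (true paths carry zero covariance).
    """

    states: pd.DataFrame
    covs: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in ("true", "filtered", "smoothed"):
            raise ValueError(f"unknown kind {self.kind!r}")
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.shape[0] != len(self.states):
            raise ValueError("covs not aligned with states")

    @property
    def q(self) -> int:
        return self.covs.shape[1]

    @property
    def factor_cols(self) -> list[str]:
        return [f"f{k + 1}" for k in range(self.q)]

    @property
    def values(self) -> np.ndarray:
        return self.states[self.factor_cols].to_numpy()

    def to_csv(self, path) -> None:
        rows = []
        est = self.values
        for k in range(self.q):
            rows.append(pd.DataFrame({
                "id": self.states["id"],
                "time": self.states["time"],
                "factor": k + 1,
                "estimate": est[:, k],
                "variance": self.covs[:, k, k],
            }))
        pd.concat(rows).sort_values(["id", "time", "factor"]).to_csv(
            path, index=False, float_format="%.10g")
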