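"""Timestamped pedestrian trajectory tables.

A :class:`TrajectoryDataset` is the lingua franca between the simulator, the
calibration estimators and the validation layer: one row per pedestrian per
sample, columns ``ped_id, t, x, y`` (seconds and meters, Cartesian frame
with the origin at the extent's lower-left corner, y up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectoryDataset"]

COLUMNS = ("ped_id", "t", "x", "y")


@dataclass
class TrajectoryDataset:
    """Trajectory records with per-pedestrian strictly increasing times."""

    df: pd.DataFrame
    sampling_interval: float | None = None
    _by_ped: dict | None = field(repr=False, default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns {missing}")
        if len(self.df) == 0:
            return
        if not np.all(np.isfinite(self.df[["t", "x", "y"]].to_numpy(dtype=float))):
            raise ValueError("trajectory table contains non-finite t/x/y values")
        order = self.df.groupby("ped_id", sort=False)["t"].diff()
        bad = order[order <= 0]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(
                f"times must be strictly increasing per pedestrian; "
                f"violated at row {row} (ped_id={self.df['ped_id'].iloc[row]!r})"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ped_ids(self) -> np.ndarray:
        return self.df["ped_id"].unique()

    @property
    def time_range(self) -> tuple[float, float]:
        t = self.df["t"].to_numpy(dtype=float)
        return float(t.min()), float(t.max())

    def by_pedestrian(self):
        """Mapping ped_id -> (t, x, y) arrays sorted by time (cached)."""
        if self._by_ped is None:
            self._by_ped = {}
            df = self.df.sort_values(["ped_id", "t"], kind="stable")
            for pid, g in df.groupby("ped_id", sort=False):
                self._by_ped[pid] = (
                    g["t"].to_numpy(dtype=float),
                    g["x"].to_numpy(dtype=float),
                    g["y"].to_numpy(dtype=float),
                )
        return self._by_ped

    def positions_at(self, t: float) -> tuple[list, np.ndarray]:
        """Linearly interpolated positions of pedestrians present at time ``t``.

        A pedestrian is present if ``t`` lies within its recorded time span.
        Returns (ids, (n, 2) array).
        """
        ids, pos = [], []
        for pid, (tt, xx, yy) in self.by_pedestrian().items():
            if tt[0] - 1e-9 <= t <= tt[-1] + 1e-9:
                ids.append(pid)
                pos.append((np.interp(t, tt, xx), np.interp(t, tt, yy)))
        return ids, np.asarray(pos, dtype=float).reshape(-1, 2)

    def speeds_at(self, t: float, half_window: float = 0.5) -> tuple[list, np.ndarray]:
        """Instantaneous speeds (central difference over ``2*half_window`` s)."""
        ids, speeds = [], []
        for pid, (tt, xx, yy) in self.by_pedestrian().items():
            if not (tt[0] - 1e-9 <= t <= tt[-1] + 1e-9):
                continue
            t0 = max(t - half_window, tt[0])
            t1 = min(t + half_window, tt[-1])
            if t1 - t0 <= 1e-9:
                continue
            dx = np.interp(t1, tt, xx) - np.interp(t0, tt, xx)
            dy = np.interp(t1, tt, yy) - np.interp(t0, tt, yy)
            ids.append(pid)
            speeds.append(float(np.hypot(dx, dy)) / (t1 - t0))
        return ids, np.asarray(speeds, dtype=float)
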