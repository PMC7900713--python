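"""Per-cell trace container and the long-format traces table."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CellTrace:
    """One cell's time series of channel intensities and FRET ratio.

    ``times`` are minutes; ``donor``/``acceptor`` are background-subtracted
    mean pixel intensities; ``ratio`` is acceptor/donor (rises with glucose).
    ``xy`` holds per-frame centroid coordinates in pixels, when known.
    """

    cell_id: int
    times: np.ndarray
    ratio: np.ndarray
    donor: Optional[np.ndarray] = None
    acceptor: Optional[np.ndarray] = None
    xy: Optional[np.ndarray] = None  # (n_frames, 2) as (x, y)
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times.shape != self.ratio.shape:
            raise ValueError("times and ratio must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("donor", "acceptor"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (len(self.times), 2):
                raise ValueError("xy must be (n_frames, 2)")

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, offset: float) -> "CellTrace":
        """Copy with the time axis shifted by ``offset`` minutes."""
        return CellTrace(
            cell_id=self.cell_id,
            times=self.times + offset,
            ratio=self.ratio.copy(),
            donor=None if self.donor is None else self.donor.copy(),
            acceptor=None if self.acceptor is None else self.acceptor.copy(),
            xy=None if self.xy is None else self.xy.copy(),
            parent_id=self.parent_id,
        )

    def window(self, t0: float, t1: float) -> "CellTrace":
        """Sub-trace with t0 <= t <= t1 (inclusive)."""
        m = (self.times >= t0) & (self.times <= t1)
        if not m.any():
            raise ValueError("window contains no samples")
        return CellTrace(
            cell_id=self.cell_id,
            times=self.times[m],
            ratio=self.ratio[m],
            donor=None if self.donor is None else self.donor[m],
            acceptor=None if self.acceptor is None else self.acceptor[m],
            xy=None if self.xy is None else self.xy[m],
            parent_id=self.parent_id,
        )


def traces_to_frame(traces: list[CellTrace], frame_interval: Optional[float] = None) -> pd.DataFrame:
    """Long-format traces table: one row per (cell, frame)."""
    rows = []
    for tr in traces:
        n = len(tr)
        d = {
            "time_min": tr.times,
            "cell_id": np.full(n, tr.cell_id, dtype=int),
            "donor_mean": tr.donor if tr.donor is not None else np.full(n, np.nan),
            "acceptor_mean": tr.acceptor if tr.acceptor is not None else np.full(n, np.nan),
            "ratio": tr.ratio,
            "x": tr.xy[:, 0] if tr.xy is not None else np.full(n, np.nan),
            "y": tr.xy[:, 1] if tr.xy is not None else np.full(n, np.nan),
            "parent_id": np.full(n, -1 if tr.parent_id is None else tr.parent_id, dtype=int),
        }
        rows.append(pd.DataFrame(d))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["time_min", "cell_id", "donor_mean", "acceptor_mean", "ratio", "x", "y", "parent_id"]
    )
    interval = frame_interval
    if interval is None and len(df):
        ts = np.unique(df["time_min"])
        interval = float(np.min(np.diff(ts))) if len(ts) > 1 else 1.0
    if len(df):
        df.insert(0, "frame", np.rint(df["time_min"] / interval).astype(int))
    else:
        df.insert(0, "frame", pd.Series(dtype=int))
    return df


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    """Inverse of :func:`traces_to_frame`."""
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        pid = int(g["parent_id"].iloc[0]) if "parent_id" in g else -1
        xy = None
        if "x" in g and np.isfinite(g["x"]).all():
            xy = np.column_stack([g["x"].to_numpy(), g["y"].to_numpy()])
        out.append(
            CellTrace(
                cell_id=int(cid),
                times=g["time_min"].to_numpy(),
                ratio=g["ratio"].to_numpy(),
                donor=g["donor_mean"].to_numpy() if np.isfinite(g["donor_mean"]).all() else None,
                acceptor=g["acceptor_mean"].to_numpy() if np.isfinite(g["acceptor_mean"]).all() else None,
                xy=xy,
                parent_id=None if pid < 0 else pid,
            )
        )
    return out
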