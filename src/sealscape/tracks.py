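"""GPS track filtering, regularisation, and dive-position merging.

Fastloc-GPS fixes are accurate but occasionally contain gross position
errors; a McConnell-style iterative speed filter removes fixes implying an
unrealistic swim speed to a neighbour. The filtered track is then linearly
interpolated to a regular clock (10 min by default) and dives are assigned
positions by linear interpolation at their start times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo

#: sustained-swim-speed ceiling for an otariid (m/s); fixes implying more are errors
DEFAULT_VMAX = 3.0


@dataclass
class Trajectory:
    """Time-ordered planar track for one individual."""

    times: np.ndarray  # s
    x: np.ndarray  # m
    y: np.ndarray  # m
    individual_id: str = ""
    regular_interval: float | None = None
    warning: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times/x/y must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def segment_speeds(self) -> np.ndarray:
        d = np.hypot(np.diff(self.x), np.diff(self.y))
        return d / np.diff(self.times)

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "x": self.x, "y": self.y})


def read_gps_csv(path, origin_lonlat, individual_id: str = "") -> Trajectory:
    """Read ``time,lon,lat`` CSV and project to planar metres about ``origin_lonlat``."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["time"], utc=True).astype("int64").to_numpy() / 1e9
    x, y = geo.project_lonlat(
        df["lon"].to_numpy(), df["lat"].to_numpy(), *origin_lonlat
    )
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    return Trajectory(times=t[keep], x=x[keep], y=y[keep], individual_id=individual_id)


def speed_filter(traj: Trajectory, vmax: float = DEFAULT_VMAX) -> Trajectory:
    """Iteratively remove fixes implying speed > ``vmax`` to a neighbour.

    Each pass removes the single worst offender (largest summed neighbour
    speed) and recomputes, until no over-speed pair remains. The first and
    last fixes are always retained. If every interior fix is removed the
    result carries ``warning="all interior fixes removed"``.
    """
    if len(traj) < 2:
        raise ValueError("need at least two fixes")
    t, x, y = traj.times.copy(), traj.x.copy(), traj.y.copy()
    idx = np.arange(len(t))
    while len(idx) > 2:
        tt, xx, yy = t[idx], x[idx], y[idx]
        v = np.hypot(np.diff(xx), np.diff(yy)) / np.diff(tt)
        bad = v > vmax
        if not bad.any():
            break
        # charge each interior fix the smaller of its two adjacent speeds:
        # a genuine spike forces both high, its innocent neighbours only one
        charge = np.minimum(v[:-1], v[1:])
        interior_bad = bad[:-1] | bad[1:]
        if not interior_bad.any():
            break  # only an endpoint segment is over-speed; endpoints are kept
        worst = int(np.argmax(np.where(interior_bad, charge, -np.inf))) + 1
        idx = np.delete(idx, worst)
    warning = None
    if len(idx) == 2 and len(traj) > 2:
        warning = "all interior fixes removed"
    return Trajectory(
        times=t[idx],
        x=x[idx],
        y=y[idx],
        individual_id=traj.individual_id,
        warning=warning,
    )


def interpolate_track(traj: Trajectory, interval: float = 600.0) -> Trajectory:
    """Linearly resample the track at ``t0, t0 + interval, ...``.

    The clock starts at the first fix and never extrapolates past the last.
    """
    if len(traj) < 2:
        raise ValueError("need at least two fixes to interpolate")
    if interval <= 0:
        raise ValueError("interval must be positive")
    t0, t1 = traj.times[0], traj.times[-1]
    n = int(np.floor((t1 - t0) / interval)) + 1
    t_new = t0 + interval * np.arange(n)
    return Trajectory(
        times=t_new,
        x=np.interp(t_new, traj.times, traj.x),
        y=np.interp(t_new, traj.times, traj.y),
        individual_id=traj.individual_id,
        regular_interval=float(interval),
    )


def merge_dives(traj: Trajectory, dives, tolerance: float = 0.0):
    """Attach a track position to each dive (interpolated at dive start).

    Returns ``(located, n_dropped)`` where ``located`` is a DataFrame with the
    dive fields plus ``x``/``y``; dives starting outside the track time span
    (beyond ``tolerance`` seconds) are dropped and counted.
    """
    from .dives import dive_table

    if traj.regular_interval is None:
        raise ValueError("trajectory must be regularised first")
    df = dive_table(dives)
    if df.empty:
        return df.assign(x=pd.Series(dtype=float), y=pd.Series(dtype=float)), 0
    t0, t1 = traj.times[0], traj.times[-1]
    inside = (df["start"] >= t0 - tolerance) & (df["start"] <= t1 + tolerance)
    n_dropped = int((~inside).sum())
    df = df[inside].reset_index(drop=True)
    ts = df["start"].to_numpy().clip(t0, t1)
    df["x"] = np.interp(ts, traj.times, traj.x)
    df["y"] = np.interp(ts, traj.times, traj.y)
    return df, n_dropped


def write_track_csv(traj: Trajectory, path, origin_lonlat=None):
    """Write the track as CSV; with ``origin_lonlat`` also writes lon/lat columns."""
    df = traj.to_frame()
    if origin_lonlat is not None:
        lon, lat = geo.unproject_xy(traj.x, traj.y, *origin_lonlat)
        df["lon"] = lon
        df["lat"] = lat
    df.to_csv(path, index=False)
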