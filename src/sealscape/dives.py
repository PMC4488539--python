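"""Dive detection and benthic/pelagic classification from time-depth records.

A time-depth recorder samples depth at a fixed interval. Processing follows
the standard biologging sequence: zero-offset correction of surface-sensor
drift, dive detection with a minimum-depth threshold (5 m), per-dive summary
statistics, and classification of each dive as benthic or pelagic.

Classification uses the bottom-weighted depth score: the proportion of the
dive spent in its bottom phase multiplied by the maximum depth. For a benthic
forager the score distribution is bimodal — deep flat-bottomed dives to the
sea floor versus shallower transiting/pelagic dives — and the nadir of a
kernel density estimate between the two modes is the class boundary: scores
below the nadir are pelagic, scores at or above it benthic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

BENTHIC = "benthic"
PELAGIC = "pelagic"
UNCLASSIFIED = "unclassified"


class UnimodalScoresError(ValueError):
    """The dive-score density has a single mode; no nadir exists."""


@dataclass
class DepthSeries:
    """Raw or corrected depth trace. Depth in metres, positive down."""

    times: np.ndarray  # seconds, strictly increasing
    depths: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape:
            raise ValueError("times and depths must have equal length")
        if self.times.size == 0:
            raise ValueError("empty depth series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        """Median sampling interval (s)."""
        if self.times.size < 2:
            return np.nan
        return float(np.median(np.diff(self.times)))


@dataclass
class DiveRecord:
    start: float
    end: float
    duration: float
    max_depth: float
    bottom_time_prop: float
    score: float
    dive_class: str = UNCLASSIFIED

    @property
    def is_benthic(self) -> bool:
        return self.dive_class == BENTHIC


def read_depth_csv(path) -> DepthSeries:
    """Read a ``time,depth_m`` CSV (ISO-8601 UTC timestamps)."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["time"], utc=True).astype("int64").to_numpy() / 1e9
    return DepthSeries(times=t, depths=df["depth_m"].to_numpy(dtype=float))


def dive_table(dives) -> pd.DataFrame:
    """One row per DiveRecord."""
    return pd.DataFrame(
        [
            {
                "start": d.start,
                "end": d.end,
                "duration": d.duration,
                "max_depth": d.max_depth,
                "bottom_time_prop": d.bottom_time_prop,
                "score": d.score,
                "dive_class": d.dive_class,
            }
            for d in dives
        ]
    )


def zero_offset_correct(
    series: DepthSeries,
    window: float = 3600.0,
    surface_quantile: float = 0.02,
) -> DepthSeries:
    """Remove surface-sensor drift from a depth trace.

    A rolling low quantile of depth over ``window`` seconds tracks the
    apparent surface; it is subtracted and the result clipped at zero. Works
    whenever the animal surfaces regularly within each window, as a diving
    central-place forager does.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = max(3, int(round(window / series.dt)))
    s = pd.Series(series.depths)
    baseline = (
        s.rolling(n_win, center=True, min_periods=1)
        .quantile(surface_quantile)
        .to_numpy()
    )
    corrected = np.clip(series.depths - baseline, 0.0, None)
    return DepthSeries(times=series.times.copy(), depths=corrected)


def detect_dives(
    series: DepthSeries,
    min_depth: float = 5.0,
    surface_threshold: float = 0.5,
    bottom_fraction: float = 0.8,
) -> list[DiveRecord]:
    """Find dives: maximal submergence intervals reaching ``min_depth``.

    A submergence runs while depth exceeds ``surface_threshold``; runs whose
    maximum depth is below ``min_depth`` are discarded. Returned dives are
    time-ordered and non-overlapping.
    """
    submerged = series.depths > surface_threshold
    if not submerged.any():
        return []
    edges = np.diff(submerged.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if submerged[0]:
        starts = np.insert(starts, 0, 0)
    if submerged[-1]:
        ends = np.append(ends, len(submerged))
    dives = []
    for i0, i1 in zip(starts, ends):
        seg_depth = series.depths[i0:i1]
        max_depth = float(seg_depth.max())
        if max_depth < min_depth:
            continue
        t = series.times[i0:i1]
        start, end = float(t[0]), float(t[-1])
        if end <= start:
            continue  # single-sample blip: no measurable duration
        prop = bottom_proportion(t, seg_depth, bottom_fraction)
        dives.append(
            DiveRecord(
                start=start,
                end=end,
                duration=end - start,
                max_depth=max_depth,
                bottom_time_prop=prop,
                score=prop * max_depth,
            )
        )
    return dives


def bottom_proportion(times, depths, bottom_fraction: float = 0.8) -> float:
    """Fraction of a dive's duration spent at depth >= ``bottom_fraction * max``.

    Time-weighted: each sample owns half the interval to each neighbour.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if times.size < 2 or times[-1] <= times[0]:
        raise ValueError("zero-duration dive")
    threshold = bottom_fraction * depths.max()
    dt = np.diff(times)
    w = np.zeros_like(times)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return float(w[depths >= threshold].sum() / w.sum())


def score_nadir(
    scores,
    grid_points: int = 512,
    bw_method: str | float = "silverman",
) -> float:
    """Nadir of the score KDE between its two main modes.

    Fits a Gaussian KDE (Silverman bandwidth by default) on a regular grid
    over ``[0, max(score)]``, takes the two highest local maxima, and returns
    the density minimum between them (ties broken toward the lower score).

    Raises :class:`UnimodalScoresError` if fewer than two modes exist.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise UnimodalScoresError("need at least two dives")
    if np.ptp(scores) == 0:
        raise UnimodalScoresError("all scores identical")
    kde = gaussian_kde(scores, bw_method=bw_method)
    grid = np.linspace(0.0, scores.max(), grid_points)
    dens = kde(grid)
    (imax,) = argrelextrema(dens, np.greater)
    # plateaus or boundary modes: include endpoints if they dominate neighbours
    if dens[0] > dens[1]:
        imax = np.insert(imax, 0, 0)
    if dens[-1] > dens[-2]:
        imax = np.append(imax, grid_points - 1)
    if imax.size < 2:
        raise UnimodalScoresError("score density is unimodal")
    top2 = imax[np.argsort(dens[imax])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    between = dens[lo : hi + 1]
    nadir_idx = lo + int(np.argmin(between))  # argmin takes first = lowest score
    return float(grid[nadir_idx])


def classify_dives(
    dives,
    bw_method: str | float = "silverman",
    grid_points: int = 512,
    fallback_threshold: float | None = None,
):
    """Label each dive benthic or pelagic by the KDE-nadir rule.

    Returns ``(labelled_dives, nadir)``. If the score density is unimodal all
    dives are returned unclassified with ``nadir = None``, unless
    ``fallback_threshold`` is given, in which case it is used as the boundary.
    """
    dives = list(dives)
    if len(dives) < 2:
        raise ValueError("need at least two dives to classify")
    scores = np.array([d.score for d in dives])
    try:
        nadir = score_nadir(scores, grid_points=grid_points, bw_method=bw_method)
    except UnimodalScoresError:
        if fallback_threshold is None:
            return [replace(d, dive_class=UNCLASSIFIED) for d in dives], None
        nadir = float(fallback_threshold)
    labelled = [
        replace(d, dive_class=PELAGIC if d.score < nadir else BENTHIC)
        for d in dives
    ]
    return labelled, nadir
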