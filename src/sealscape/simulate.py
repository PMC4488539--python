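"""Synthetic seascapes, structures, foraging trips and depth traces.

The generator emulates the study conditions of a central-place benthic
forager on a shallow continental shelf: a near-uniform bathymetry around a
60 m mean depth with low relief, sparse anthropogenic structures (pipelines,
cable routes, wells, shipwrecks), multi-day foraging trips that leave and
return to a colony, continuous diving (benthic dives while transiting mixed
with shallower pelagic dives), and intensive foraging bouts at discrete
patches. Patch placement can be biased toward structures with a tunable
attraction strength, giving every downstream stage a known ground truth.

Movement is a two-state correlated random walk: directed transit at cruising
speed with low turning variance, and slow tortuous search within a patch.
Ground truth is returned per dive: its bout membership, whether the bout's
patch was placed on a structure, and its true benthic/pelagic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .covariates import Grid
from .dives import DepthSeries
from .structures import StructureSet

#: epoch base for synthetic timestamps (2010-01-01 UTC)
TIME_BASE = 1262304000.0


@dataclass
class SeascapeSpec:
    """Dimensions and content of a synthetic shelf seascape."""

    n_rows: int = 160
    n_cols: int = 160
    cell_size: float = 250.0
    mean_depth: float = 60.0       # m, shelf average
    relief_amplitude: float = 5.0  # m, ~3 sd of the smooth depth anomaly
    relief_scale_cells: float = 8.0
    n_pipelines: int = 2
    n_cables: int = 1
    n_wells: int = 8
    n_shipwrecks: int = 5

    def __post_init__(self):
        if self.n_rows < 3 or self.n_cols < 3 or self.cell_size <= 0:
            raise ValueError("seascape dimensions must be positive (>= 3x3 cells)")


@dataclass
class Seascape:
    grid: Grid
    bathymetry: np.ndarray  # m positive down
    colony: tuple  # (x, y)
    coastline: LineString
    structures: StructureSet

    def depth_at(self, x, y) -> np.ndarray:
        row, col = self.grid.cell_of(x, y)
        row = np.clip(row, 0, self.grid.n_rows - 1)
        col = np.clip(col, 0, self.grid.n_cols - 1)
        return self.bathymetry[row, col]


@dataclass
class TripSpec:
    """Ground-truth knobs for one synthetic foraging trip."""

    duration_d: float | None = None  # None: drawn uniformly from duration_range
    duration_range: tuple = (3.0, 7.0)
    fix_interval: float = 300.0      # s between GPS fixes
    dive_rate: float = 6.0           # dives per hour
    attraction_strength: float = 0.0  # 0 = neutral patch placement
    attraction_targets: tuple = ("pipeline", "cable", "well", "shipwreck")
    seed: int = 0
    # movement / behaviour
    n_patches: int = 3
    transit_speed: float = 1.2       # m/s
    forage_speed: float = 0.35       # m/s
    patch_radius: float = 1000.0     # m
    forage_time_frac: float = 0.4    # share of trip spent in bouts
    pelagic_fraction_transit: float = 0.6
    gps_noise: float = 25.0          # m, 1 sd
    outlier_rate: float = 0.005      # per fix
    outlier_scale: float = 5000.0    # m
    depth_dt: float = 5.0            # s depth sampling
    depth_offset_drift: float = 0.0  # m of sensor drift over the trip

    def __post_init__(self):
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        if self.duration_d is not None and not (
            self.duration_range[0] <= self.duration_d <= self.duration_range[1]
        ):
            raise ValueError(
                f"duration must lie in {self.duration_range} days"
            )


@dataclass
class SimulatedTrip:
    """A trip as the pipeline would ingest it, plus ground truth."""

    fixes: pd.DataFrame        # time, x, y (noisy GPS, planar m)
    depth: DepthSeries
    truth: pd.DataFrame        # per dive: start, duration, max_depth, bout_id, ...
    path_times: np.ndarray     # true 60 s path (no noise)
    path_x: np.ndarray
    path_y: np.ndarray
    spec: TripSpec


def generate_seascape(spec: SeascapeSpec | None = None, seed: int = 0) -> Seascape:
    """Reproducible low-relief shelf with sparse structures.

    The coast runs along the northern grid edge with the colony just offshore
    at its midpoint. Structures are kept >= 3 km from the colony so structure
    occupancy reflects foraging choices, not colony attendance.
    """
    spec = spec or SeascapeSpec()
    rng = np.random.default_rng(seed)
    grid = Grid(
        x0=0.0,
        y0=spec.n_rows * spec.cell_size,
        cell_size=spec.cell_size,
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
    )
    if spec.relief_amplitude > 0:
        field_ = gaussian_filter(
            rng.standard_normal(grid.shape), sigma=spec.relief_scale_cells
        )
        field_ *= (spec.relief_amplitude / 3.0) / max(field_.std(), 1e-12)
    else:
        field_ = np.zeros(grid.shape)
    bathy = spec.mean_depth + field_ - field_.mean()

    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size
    coastline = LineString([(0.0, height), (width, height)])
    colony = (width / 2.0, height - 2.0 * spec.cell_size)

    margin = 2 * spec.cell_size

    def random_point(min_colony_dist=3000.0):
        while True:
            x = rng.uniform(margin, width - margin)
            y = rng.uniform(margin, height - margin)
            if np.hypot(x - colony[0], y - colony[1]) >= min_colony_dist:
                return x, y

    def random_polyline():
        x0, y0 = random_point()
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 0.8) * min(width, height)
        n_seg = rng.integers(4, 7)
        pts = [(x0, y0)]
        for k in range(1, n_seg + 1):
            a = angle + rng.normal(0, 0.25)
            x = x0 + np.cos(a) * length * k / n_seg + rng.normal(0, 500)
            y = y0 + np.sin(a) * length * k / n_seg + rng.normal(0, 500)
            pts.append(
                (float(np.clip(x, margin, width - margin)),
                 float(np.clip(y, margin, height - margin)))
            )
        return LineString(pts)

    structures = StructureSet(
        pipelines=[random_polyline() for _ in range(spec.n_pipelines)],
        cables=[random_polyline() for _ in range(spec.n_cables)],
        wells=[Point(*random_point()) for _ in range(spec.n_wells)],
        shipwrecks=[Point(*random_point()) for _ in range(spec.n_shipwrecks)],
    )
    return Seascape(
        grid=grid,
        bathymetry=bathy,
        colony=colony,
        coastline=coastline,
        structures=structures,
    )


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _place_patches(seascape: Seascape, spec: TripSpec, rng) -> list:
    """Patch centres; biased toward structures with prob a/(1+a) each."""
    grid = seascape.grid
    xmin, xmax, ymin, ymax = grid.extent
    margin = 2 * grid.cell_size
    cx, cy = seascape.colony
    max_range = 0.4 * min(xmax - xmin, ymax - ymin)

    target_geoms = seascape.structures.geometries(spec.attraction_targets)
    if spec.attraction_strength > 0 and not target_geoms:
        raise ValueError(
            "attraction requested but no structures of the targeted types exist"
        )
    p_struct = spec.attraction_strength / (1.0 + spec.attraction_strength)
    patches = []
    for _ in range(spec.n_patches):
        if target_geoms and rng.uniform() < p_struct:
            geom = target_geoms[rng.integers(len(target_geoms))]
            if isinstance(geom, LineString):
                pt = geom.interpolate(rng.uniform(0, geom.length))
            else:
                pt = geom
            x = pt.x + rng.normal(0, 150.0)
            y = pt.y + rng.normal(0, 150.0)
            driven = True
        else:
            while True:
                r = max_range * np.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * np.pi)
                x, y = cx + r * np.cos(a), cy + r * np.sin(a)
                if xmin + margin < x < xmax - margin and ymin + margin < y < ymax - margin:
                    break
            driven = False
        x = float(np.clip(x, xmin + margin, xmax - margin))
        y = float(np.clip(y, ymin + margin, ymax - margin))
        if np.hypot(x - cx, y - cy) < 2000.0:  # keep bouts away from the colony
            x = cx + 2000.0 * np.cos(rng.uniform(0, 2 * np.pi))
            y = cy - abs(2000.0 * np.sin(rng.uniform(0, 2 * np.pi)))
        patches.append({"x": x, "y": y, "structure_driven": driven})
    return patches


def _simulate_path(seascape: Seascape, spec: TripSpec, patches, rng):
    """Two-state CRW visiting the patches in order, returning to the colony.

    Returns (times, x, y, state) at 60 s resolution; state is the bout index
    during foraging, -1 in transit/homing.
    """
    dt = 60.0
    T = (
        spec.duration_d
        if spec.duration_d is not None
        else rng.uniform(*spec.duration_range)
    ) * 86400.0
    n_max = int(T / dt) + 2
    cx, cy = seascape.colony
    bout_total = spec.forage_time_frac * T
    shares = rng.dirichlet(np.full(len(patches), 6.0)) if patches else []
    bout_left = [bout_total * s for s in shares]

    xs, ys, states = [cx], [cy], [-1]
    heading = rng.uniform(0, 2 * np.pi)
    mode = "transit"  # transit -> forage (xN) -> homing
    patch_i = 0
    t = 0.0
    while len(xs) < n_max:
        x, y = xs[-1], ys[-1]
        t = len(xs) * dt
        time_left = T - t
        dist_home = np.hypot(x - cx, y - cy)
        if mode != "homing" and time_left * spec.transit_speed < 1.3 * dist_home + 2000:
            mode = "homing"
        if mode == "homing" and dist_home < 300.0:
            break
        if mode == "transit" and patch_i < len(patches):
            px, py = patches[patch_i]["x"], patches[patch_i]["y"]
            if np.hypot(x - px, y - py) < spec.patch_radius / 2:
                mode = "forage"
        if mode == "transit" and patch_i >= len(patches):
            mode = "homing"

        if mode == "forage":
            patch = patches[patch_i]
            bout_left[patch_i] -= dt
            if bout_left[patch_i] <= 0:
                patch_i += 1
                mode = "transit" if patch_i < len(patches) else "homing"
            speed = spec.forage_speed
            heading = heading + rng.normal(0, 1.4)
            # soft tether to the patch centre
            dx, dy = patch["x"] - x, patch["y"] - y
            if np.hypot(dx, dy) > spec.patch_radius:
                heading = np.arctan2(dy, dx) + rng.normal(0, 0.5)
            state = patch_i if mode == "forage" else -1
        else:
            if mode == "homing":
                tx, ty = cx, cy
            else:
                tx, ty = patches[patch_i]["x"], patches[patch_i]["y"]
            speed = spec.transit_speed
            bearing = np.arctan2(ty - y, tx - x)
            heading = bearing + 0.25 * _wrap(heading - bearing) + rng.normal(0, 0.25)
            state = -1
        xs.append(x + speed * dt * np.cos(heading))
        ys.append(y + speed * dt * np.sin(heading))
        states.append(state)
    # close the trip at the colony
    xs.append(cx)
    ys.append(cy)
    states.append(-1)
    times = dt * np.arange(len(xs))
    return times, np.array(xs), np.array(ys), np.array(states)


def _benthic_profile(duration, max_depth, bottom_prop, rng):
    """Knot times/depths of a flat-bottomed (square-ish) dive."""
    bt = bottom_prop * duration
    ramp = (duration - bt) / 2
    return [0, ramp, duration - ramp, duration], [0, max_depth, max_depth, 0]


def _pelagic_profile(duration, max_depth):
    """V-shaped dive."""
    return [0, duration / 2, duration], [0, max_depth, 0]


def generate_trip(seascape: Seascape, spec: TripSpec) -> SimulatedTrip:
    """One synthetic foraging trip with GPS fixes, depth trace and truth labels."""
    rng = np.random.default_rng(spec.seed)
    patches = _place_patches(seascape, spec, rng)
    times, px, py, state = _simulate_path(seascape, spec, patches, rng)
    T = times[-1]

    # --- GPS fixes: subsample true path, add noise and occasional outliers
    step = max(1, int(round(spec.fix_interval / 60.0)))
    idx = np.arange(0, len(times), step)
    if idx[-1] != len(times) - 1:
        idx = np.append(idx, len(times) - 1)
    gx = px[idx] + rng.normal(0, spec.gps_noise, idx.size)
    gy = py[idx] + rng.normal(0, spec.gps_noise, idx.size)
    out_mask = rng.uniform(size=idx.size) < spec.outlier_rate
    out_mask[[0, -1]] = False
    gx[out_mask] += rng.normal(0, spec.outlier_scale, out_mask.sum())
    gy[out_mask] += rng.normal(0, spec.outlier_scale, out_mask.sum())
    fixes = pd.DataFrame({"time": TIME_BASE + times[idx], "x": gx, "y": gy})

    # --- dive sequence
    period = 3600.0 / spec.dive_rate
    dive_rows = []
    t = rng.uniform(0, period / 2)
    while t < T - 400:
        duration = min(rng.uniform(120, 240), 0.8 * period)
        k = min(int(t / 60.0), len(px) - 1)
        local = float(
            seascape.depth_at(np.array([px[k]]), np.array([py[k]]))[0]
        )
        bout_id = int(state[k])
        in_bout = bout_id >= 0
        benthic = in_bout or (rng.uniform() > spec.pelagic_fraction_transit)
        if benthic:
            max_depth = max(local + rng.normal(0, 0.5), 6.0)
            knots = _benthic_profile(duration, max_depth, rng.uniform(0.55, 0.8), rng)
        else:
            max_depth = max(rng.uniform(0.2, 0.45) * local, 6.0)
            knots = _pelagic_profile(duration, max_depth)
        dive_rows.append(
            {
                "start": t,
                "duration": duration,
                "max_depth": max_depth,
                "bout_id": bout_id,
                "structure_driven": bool(
                    in_bout and patches[bout_id]["structure_driven"]
                ),
                "benthic_true": bool(benthic),
                "knots_t": knots[0],
                "knots_d": knots[1],
            }
        )
        t += period * rng.uniform(0.85, 1.15)

    # --- depth trace
    n_samp = int(T / spec.depth_dt) + 1
    tt = spec.depth_dt * np.arange(n_samp)
    depths = np.zeros(n_samp)
    for d in dive_rows:
        i0 = int(np.ceil(d["start"] / spec.depth_dt))
        i1 = min(int((d["start"] + d["duration"]) / spec.depth_dt), n_samp - 1)
        rel = tt[i0 : i1 + 1] - d["start"]
        depths[i0 : i1 + 1] = np.interp(rel, d["knots_t"], d["knots_d"])
    if spec.depth_offset_drift:
        depths = np.clip(depths + spec.depth_offset_drift * tt / T, 0, None)
    depth = DepthSeries(times=TIME_BASE + tt, depths=depths)

    truth = pd.DataFrame(
        [
            {
                "start": TIME_BASE + d["start"],
                "duration": d["duration"],
                "max_depth": d["max_depth"],
                "bout_id": d["bout_id"],
                "structure_driven": d["structure_driven"],
                "benthic_true": d["benthic_true"],
            }
            for d in dive_rows
        ]
    )
    return SimulatedTrip(
        fixes=fixes,
        depth=depth,
        truth=truth,
        path_times=TIME_BASE + times,
        path_x=px,
        path_y=py,
        spec=spec,
    )


def two_patch_track(
    patch_radius: float = 1000.0,
    speed: float = 1.0,
    interval: float = 600.0,
    bout_hours: float = 5.0,
    transit_km: float = 10.0,
    dive_fraction: float = 0.4,
    seed: int = 0,
):
    """Idealised two-patch movement for validating first-passage scale selection.

    The animal travels at one speed throughout: straight transit between the
    colony and two patches, and a hard-reflected random walk confined to a
    disc of ``patch_radius`` during each bout. Because movement inside and
    outside patches differs only in confinement, the variance of log
    first-passage values peaks at the patch scale. Returns
    ``(trajectory, underwater_seconds)`` with a uniform dive fraction.
    """
    from .tracks import Trajectory

    rng = np.random.default_rng(seed)
    pts = [np.array([0.0, 0.0])]
    step = speed * interval

    def transit(to):
        while np.linalg.norm(pts[-1] - to) > step:
            d = to - pts[-1]
            pts.append(pts[-1] + step * d / np.linalg.norm(d))

    def bounce(center, hours):
        for _ in range(int(hours * 3600 / interval)):
            cand = pts[-1]
            for _ in range(50):
                a = rng.uniform(0, 2 * np.pi)
                cand = pts[-1] + step * np.array([np.cos(a), np.sin(a)])
                if np.linalg.norm(cand - center) <= patch_radius:
                    break
            pts.append(cand)

    c1 = np.array([transit_km * 1000.0, 0.0])
    c2 = np.array([transit_km * 1000.0, transit_km * 1000.0])
    transit(c1)
    bounce(c1, bout_hours)
    transit(c2)
    bounce(c2, bout_hours)
    transit(np.array([0.0, 0.0]))
    P = np.array(pts)
    traj = Trajectory(
        times=interval * np.arange(len(P)),
        x=P[:, 0],
        y=P[:, 1],
        regular_interval=interval,
    )
    underwater = np.full(len(traj), dive_fraction * interval)
    underwater[-1] = 0.0
    return traj, underwater


# ---------------------------------------------------------------------------
# On-disk output in the formats the pipeline reads


def write_trip(trip: SimulatedTrip, gps_path, depth_path, truth_path, origin_lonlat):
    from . import geo

    lon, lat = geo.unproject_xy(
        trip.fixes["x"].to_numpy(), trip.fixes["y"].to_numpy(), *origin_lonlat
    )
    gps = pd.DataFrame(
        {
            "time": pd.to_datetime(trip.fixes["time"], unit="s", utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "lon": lon,
            "lat": lat,
        }
    )
    gps.to_csv(gps_path, index=False)
    pd.DataFrame(
        {
            "time": pd.to_datetime(trip.depth.times, unit="s", utc=True).strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "depth_m": trip.depth.depths,
        }
    ).to_csv(depth_path, index=False)
    trip.truth.to_csv(truth_path, index=False)
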