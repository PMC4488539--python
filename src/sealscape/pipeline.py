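"""End-to-end pipeline: dives -> track -> FPD -> covariates -> model -> occupancy -> stats.

Runs every individual of a cohort through the full analysis and writes
per-seal and cohort-level outputs with a manifest. A seal failing a stage
(e.g. fewer than 5 presence cells for the habitat model) is reported with
empty model fields and skipped, not fatal — matching how individuals with
insufficient dive locations are carried in the field study's summary table.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, covariates, dives, fpd, geo, maxent, tracks
from .simulate import SeascapeSpec, TripSpec, generate_seascape, generate_trip, write_trip
from .structures import StructureSet

log = logging.getLogger("sealscape")

STAGES = ("dives", "track", "fpd", "covariates", "model", "occupancy", "stats")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    # paths
    data_dir: str = "."
    tracks_dir: str = "tracks"
    depths_dir: str = "depths"
    structures_file: str = "structures.geojson"
    bathymetry_file: str = "bathymetry.asc"
    coastline_file: str = "coastline.geojson"
    out_dir: str = "output"
    # geography
    origin_lon: float = 146.3
    origin_lat: float = -39.15
    colony_lon: float = 146.3
    colony_lat: float = -39.15
    # parameters
    min_depth: float = 5.0
    zoc_window: float = 3600.0
    interval: float = 600.0
    vmax: float = 3.0
    buffer: float = 250.0
    train_frac: float = 0.7
    background_n: int = 10_000
    reg_multiplier: float = 1.0
    tol: float = 1e-5
    max_iter: int = 1000
    radii_min: float = 250.0
    radii_max: float = 20_000.0
    n_radii: int = 15
    quantile: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.min_depth <= 0 or self.interval <= 0 or self.buffer <= 0:
            raise ValueError("min_depth, interval and buffer must be positive")
        if self.radii_min <= 0 or self.radii_max <= self.radii_min:
            raise ValueError("radii range must be positive and increasing")

    def path(self, name: str) -> Path:
        return Path(self.data_dir) / getattr(self, name)

    @property
    def radii(self) -> np.ndarray:
        return np.geomspace(self.radii_min, self.radii_max, self.n_radii)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs: dict = {}
        valid = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for section in cp.sections():
            for key, val in cp.items(section):
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = val
        cfg = cls(**{k: _coerce(cls, k, v) for k, v in kwargs.items()})
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, _coerce(cls, k, v))
        return cfg

    def to_file(self, path):
        cp = configparser.ConfigParser()
        path_keys = {
            "data_dir", "tracks_dir", "depths_dir", "structures_file",
            "bathymetry_file", "coastline_file", "out_dir",
        }
        geo_keys = {"origin_lon", "origin_lat", "colony_lon", "colony_lat"}
        cp["paths"] = {}
        cp["geography"] = {}
        cp["parameters"] = {}
        for k, v in asdict(self).items():
            section = (
                "paths" if k in path_keys
                else "geography" if k in geo_keys
                else "parameters"
            )
            cp[section][k] = str(v)
        with open(path, "w") as fh:
            cp.write(fh)


def _coerce(cls, key, value):
    import dataclasses

    ftype = next(
        f.type for f in dataclasses.fields(cls) if f.name == key
    )
    if isinstance(value, str):
        if ftype in ("int", int):
            return int(value)
        if ftype in ("float", float):
            return float(value)
    return value


@dataclass
class SealResult:
    individual_id: str
    n_dives: int = 0
    n_benthic: int = 0
    nadir: float | None = None
    scale_m: float | None = None
    foraging_cells: int | None = None
    auc: float | None = None
    contributions: dict = field(default_factory=dict)
    occupancy: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class PipelineResult:
    per_seal: pd.DataFrame
    occupancy: pd.DataFrame
    cohort: dict
    seal_results: list


def _coastline_from(cfg, grid):
    from shapely.geometry import LineString, shape

    path = cfg.path("coastline_file")
    if path.exists():
        with open(path) as fh:
            gj = json.load(fh)
        feat = gj["features"][0] if gj.get("type") == "FeatureCollection" else gj
        return shape(feat.get("geometry", feat))
    xmin, xmax, _, ymax = grid.extent
    return LineString([(xmin, ymax), (xmax, ymax)])


def run_pipeline(cfg: PipelineConfig, through: str = "stats") -> PipelineResult:
    """Execute the pipeline for every individual found in ``tracks_dir``.

    ``through`` stops after the named stage (one of ``STAGES``); per-stage
    record counts are logged and all outputs land under ``cfg.out_dir``.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    stop = STAGES.index(through)
    out = Path(cfg.data_dir) / cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    origin = (cfg.origin_lon, cfg.origin_lat)
    grid, bathy = covariates.read_esri_ascii(cfg.path("bathymetry_file"))
    structures = StructureSet.read_geojson(cfg.path("structures_file"))
    colony_xy = tuple(
        float(np.asarray(v).item())
        for v in geo.project_lonlat(cfg.colony_lon, cfg.colony_lat, *origin)
    )
    coastline = _coastline_from(cfg, grid)

    stack = None
    if stop >= STAGES.index("covariates"):
        stack = covariates.build_stack(grid, bathy, colony_xy, coastline, structures)
        for name, layer in stack.layers.items():
            covariates.write_esri_ascii(out / f"layer_{name}.asc", grid, layer)
        background = maxent.sample_background(
            stack,
            n=min(cfg.background_n, grid.n_rows * grid.n_cols),
            seed=cfg.seed,
        )
        vif = covariates.vif_screen(background[list(covariates.LAYER_NAMES)])
        vif.to_csv(out / "vif.csv", index=False)
        log.info("covariates: 7 layers on %dx%d grid; max VIF %.2f",
                 grid.n_rows, grid.n_cols, vif["vif"].max())
    else:
        background = None

    track_files = sorted(Path(cfg.path("tracks_dir")).glob("*.csv"))
    if not track_files:
        raise FileNotFoundError(f"no track CSVs in {cfg.path('tracks_dir')}")

    results: list[SealResult] = []
    for tf in track_files:
        sid = tf.stem
        res = SealResult(individual_id=sid)
        results.append(res)
        try:
            _run_seal(cfg, tf, res, stop, out, origin, grid, stack, background, structures)
        except (ValueError, maxent.InsufficientPresencesError) as err:
            res.note = res.note or str(err)
            log.warning("%s failed a stage and was skipped: %s", sid, err)

    # --- cohort outputs
    per_seal = _per_seal_table(results)
    per_seal.to_csv(out / "per_seal.csv", index=False)
    occ_df = pd.DataFrame([r.occupancy for r in results if r.occupancy])
    if not occ_df.empty:
        occ_df.to_csv(out / "occupancy.csv", index=False)

    cohort: dict = {"n_seals": len(results)}
    if stop >= STAGES.index("stats"):
        cohort.update(_cohort_stats(results, per_seal))
        (out / "cohort_summary.json").write_text(json.dumps(cohort, indent=2))

    manifest = {
        "package": "sealscape",
        "version": __version__,
        "config": asdict(cfg),
        "inputs": [str(tf) for tf in track_files],
        "stages_run": STAGES[: stop + 1],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        per_seal=per_seal, occupancy=occ_df, cohort=cohort, seal_results=results
    )


def _run_seal(cfg, tf, res, stop, out, origin, grid, stack, background, structures):
    sid = res.individual_id
    # --- dives
    series = dives.read_depth_csv(Path(cfg.path("depths_dir")) / tf.name)
    series = dives.zero_offset_correct(series, window=cfg.zoc_window)
    dive_list = dives.detect_dives(series, min_depth=cfg.min_depth)
    res.n_dives = len(dive_list)
    if len(dive_list) >= 2:
        dive_list, nadir = dives.classify_dives(
            dive_list, fallback_threshold=0.0
        )
        res.nadir = nadir
    res.n_benthic = sum(d.is_benthic for d in dive_list)
    dives.dive_table(dive_list).to_csv(out / f"{sid}_dives.csv", index=False)
    log.info("%s dives: %d detected, %d benthic", sid, res.n_dives, res.n_benthic)
    if stop == 0:
        return

    # --- track
    traj = tracks.read_gps_csv(tf, origin, individual_id=sid)
    n_raw = len(traj)
    traj = tracks.speed_filter(traj, vmax=cfg.vmax)
    traj = tracks.interpolate_track(traj, interval=cfg.interval)
    located, n_dropped = tracks.merge_dives(traj, dive_list)
    tracks.write_track_csv(traj, out / f"{sid}_track.csv", origin)
    located.to_csv(out / f"{sid}_located_dives.csv", index=False)
    log.info(
        "%s track: %d raw fixes -> %d regular; %d dives dropped outside span",
        sid, n_raw, len(traj), n_dropped,
    )
    if stop == 1:
        return

    # --- FPD
    under = fpd.attach_underwater_time(traj, dive_list)
    sel = fpd.select_scale(traj, under, radii=cfg.radii)
    res.scale_m = sel.radius
    if sel.warning:
        log.warning("%s fpd: %s", sid, sel.warning)
    events = fpd.intensive_areas(
        traj, under, located, sel.radius, grid, quantile=cfg.quantile
    )
    fpd.events_table(events).to_csv(out / f"{sid}_events.csv", index=False)
    fpd.write_events_geojson(events, out / f"{sid}_events.geojson")
    log.info("%s fpd: scale %.0f m, %d foraging cells", sid, sel.radius, len(events))
    if stop == 2:
        return

    # --- covariate extraction
    presence = covariates.extract_covariates(stack, fpd.events_table(events).rename(
        columns={"row": "grid_row", "col": "grid_col"}
    )) if events else pd.DataFrame(columns=["grid_row", "grid_col", *stack.names])
    res.foraging_cells = len(presence)
    presence.to_csv(out / f"{sid}_presence.csv", index=False)
    if stop == 3:
        return

    # --- habitat model
    if stop >= 4:
        try:
            train, test = maxent.partition_data(
                presence, train_frac=cfg.train_frac,
                seed=cfg.seed + _stable_id(sid),
            )
            model = maxent.MaxentHabitatModel(
                train[list(covariates.LAYER_NAMES)],
                background,
                variables=list(covariates.LAYER_NAMES),
                reg_multiplier=cfg.reg_multiplier,
            )
            fit = model.fit(tol=cfg.tol, max_iter=cfg.max_iter)
            res.auc = fit.auc(test) if len(test) else None
            res.contributions = fit.contributions().to_dict()
            (out / f"{sid}_model.json").write_text(fit.to_json())
            log.info("%s model: AUC %.3f over %d presence cells",
                     sid, res.auc if res.auc else float("nan"), len(presence))
        except maxent.InsufficientPresencesError as err:
            res.note = str(err)
            log.warning("%s model skipped: %s", sid, err)
    if stop == 4:
        return

    # --- occupancy
    occ = association.buffer_occupancy(traj, structures, radius=cfg.buffer)
    res.occupancy = occ.to_row()


def _stable_id(sid: str) -> int:
    return sum(ord(c) * 31**i for i, c in enumerate(sid)) % 100_000


def _per_seal_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "individual_id": r.individual_id,
            "n_dives": r.n_dives,
            "n_benthic": r.n_benthic,
            "scale_m": r.scale_m,
            "foraging_cells": r.foraging_cells,
            "auc": r.auc,
            "note": r.note,
        }
        for name in covariates.LAYER_NAMES:
            row[f"contrib_{name}"] = r.contributions.get(name)
        if r.occupancy:
            row["any_structure_prop"] = r.occupancy.get("any_structure_prop")
            row["n_types_visited"] = r.occupancy.get("n_types_visited")
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_stats(results, per_seal: pd.DataFrame) -> dict:
    out: dict = {}
    occ_summaries = []
    for r in results:
        if r.occupancy:
            s = association.OccupancySummary(
                individual_id=r.individual_id,
                trip_duration=r.occupancy["trip_duration_s"],
                seconds_by_type={
                    k[: -len("_s")]: v
                    for k, v in r.occupancy.items()
                    if k.endswith("_s") and k not in (
                        "trip_duration_s", "any_structure_s"
                    )
                },
                any_structure_seconds=r.occupancy["any_structure_s"],
            )
            occ_summaries.append(s)
    if occ_summaries:
        out["structure_use"] = association.summarize_structure_use(occ_summaries)
    cols = ["contrib_d_pipes_cables", "contrib_d_wells", "contrib_d_shipwrecks"]
    modelled = per_seal.dropna(subset=cols)
    out["n_modelled"] = int(len(modelled))
    if len(modelled) >= 2:
        groups = [modelled[c].to_numpy() for c in cols]
        H, dfree, p = association.kruskal_wallis(*groups)
        out["structure_type_kruskal"] = {"H": H, "df": dfree, "p": p}
        out["mean_structure_contrib"] = {
            c.removeprefix("contrib_d_"): float(modelled[c].mean()) for c in cols
        }
        total = modelled[cols].sum(axis=1)
        out["n_structure_gt30"] = int((total > 30).sum())
        out["mean_combined_structure_contrib"] = float(total.mean())
    return out


def analyze_trip(
    trip,
    grid,
    stack,
    background,
    structures,
    interval: float = 600.0,
    quantile: float = 0.75,
    train_frac: float = 0.7,
    seed: int = 0,
    buffer: float = 250.0,
) -> SealResult:
    """In-memory analysis of one simulated trip (no file round trip).

    Runs dive processing, track regularisation, FPD, presence extraction,
    the habitat model and buffer occupancy, returning a :class:`SealResult`.
    """
    series = dives.zero_offset_correct(trip.depth)
    dive_list = dives.detect_dives(series)
    res = SealResult(individual_id=f"sim_{seed}", n_dives=len(dive_list))
    if len(dive_list) >= 2:
        dive_list, res.nadir = dives.classify_dives(dive_list, fallback_threshold=0.0)
    res.n_benthic = sum(d.is_benthic for d in dive_list)
    traj = tracks.Trajectory(
        times=trip.fixes["time"].to_numpy(),
        x=trip.fixes["x"].to_numpy(),
        y=trip.fixes["y"].to_numpy(),
    )
    traj = tracks.interpolate_track(tracks.speed_filter(traj), interval)
    located, _ = tracks.merge_dives(traj, dive_list)
    under = fpd.attach_underwater_time(traj, dive_list)
    sel = fpd.select_scale(traj, under)
    res.scale_m = sel.radius
    events = fpd.intensive_areas(traj, under, located, sel.radius, grid, quantile=quantile)
    presence = (
        covariates.extract_covariates(
            stack,
            fpd.events_table(events).rename(columns={"row": "grid_row", "col": "grid_col"}),
        )
        if events
        else pd.DataFrame(columns=["grid_row", "grid_col", *stack.names])
    )
    res.foraging_cells = len(presence)
    try:
        train, test = maxent.partition_data(presence, train_frac=train_frac, seed=seed)
        fit = maxent.MaxentHabitatModel(
            train[list(covariates.LAYER_NAMES)],
            background,
            variables=list(covariates.LAYER_NAMES),
        ).fit()
        res.auc = fit.auc(test) if len(test) else None
        res.contributions = fit.contributions().to_dict()
    except maxent.InsufficientPresencesError as err:
        res.note = str(err)
    res.occupancy = association.buffer_occupancy(traj, structures, radius=buffer).to_row()
    return res


# ---------------------------------------------------------------------------
# Synthetic cohort on disk


def simulate_cohort(
    out_dir,
    n_seals: int = 6,
    seed: int = 0,
    seascape_spec: SeascapeSpec | None = None,
    trip_kwargs: dict | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a complete synthetic input layout consumable by :func:`run_pipeline`.

    Returns the path of the generated config file.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists; pass overwrite=True")
    (out_dir / "tracks").mkdir(parents=True, exist_ok=True)
    (out_dir / "depths").mkdir(exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)

    seascape = generate_seascape(seascape_spec, seed=seed)
    covariates.write_esri_ascii(
        out_dir / "bathymetry.asc", seascape.grid, seascape.bathymetry
    )
    seascape.structures.write_geojson(out_dir / "structures.geojson")
    with open(out_dir / "coastline.geojson", "w") as fh:
        from shapely.geometry import mapping

        json.dump(
            {
                "type": "Feature",
                "geometry": mapping(seascape.coastline),
                "properties": {},
            },
            fh,
        )

    origin = (146.3, -39.15)
    colony_lon, colony_lat = geo.unproject_xy(*seascape.colony, *origin)
    trip_kwargs = dict(trip_kwargs or {})
    for i in range(n_seals):
        spec = TripSpec(seed=seed * 1000 + i + 1, **trip_kwargs)
        trip = generate_trip(seascape, spec)
        sid = f"seal_{i + 1:02d}"
        write_trip(
            trip,
            out_dir / "tracks" / f"{sid}.csv",
            out_dir / "depths" / f"{sid}.csv",
            out_dir / "truth" / f"{sid}.csv",
            origin,
        )

    cfg = PipelineConfig(
        data_dir=str(out_dir),
        origin_lon=origin[0],
        origin_lat=origin[1],
        colony_lon=float(colony_lon),
        colony_lat=float(colony_lat),
        seed=seed,
    )
    cfg.to_file(out_dir / "config.ini")
    return out_dir / "config.ini"
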