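"""Gridded covariate stack for habitat modelling.

Seven explanatory layers on a shared 250 m grid: water depth, sea-floor
terrain complexity (second derivative of slope on a 3x3 neighbourhood), and
Euclidean distances to the colony, the coast, pipelines/cables, wells and
shipwrecks. Also the collinearity screen (variance inflation factors).

Grid convention: rows run north to south. Cell ``(i, j)`` covers the
half-open square ``[x0 + j*c, x0 + (j+1)*c) x (y0 - (i+1)*c, y0 - i*c]``
where ``(x0, y0)`` is the north-west corner and ``c`` the cell size; layer
values are sampled at cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

LAYER_NAMES = (
    "depth",
    "complexity",
    "d_colony",
    "d_coast",
    "d_pipes_cables",
    "d_wells",
    "d_shipwrecks",
)


@dataclass(frozen=True)
class Grid:
    """Regular planar raster grid, north-up."""

    x0: float  # west edge (m)
    y0: float  # north edge (m)
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self):
        return (self.n_rows, self.n_cols)

    @property
    def extent(self):
        """(xmin, xmax, ymin, ymax)."""
        return (
            self.x0,
            self.x0 + self.n_cols * self.cell_size,
            self.y0 - self.n_rows * self.cell_size,
            self.y0,
        )

    def cell_centers(self):
        """Meshgrid arrays (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x, y):
        """(row, col) indices of the cells containing points ``(x, y)``.

        Points outside the grid get indices outside ``[0, n_rows) x [0, n_cols)``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        # points exactly on the north/west edges belong to the first row/col
        row = np.where(np.isclose(y, self.y0), 0, row)
        return row, col

    def contains_cell(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_esri_ascii(path, grid: Grid, values: np.ndarray, nodata: float = -9999.0):
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0:.6f}\n"
        f"yllcorner {grid.y0 - grid.n_rows * grid.cell_size:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_esri_ascii(path):
    """Read an ESRI ASCII grid. Returns ``(grid, values)`` with NODATA as NaN."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError("grid body does not match declared dimensions")
    cell = header["cellsize"]
    grid = Grid(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(np.isclose(values, nodata), np.nan, values)
    return grid, values


# ---------------------------------------------------------------------------
# Layers


def distance_raster(grid: Grid, geometries) -> np.ndarray:
    """Exact planar Euclidean distance from every cell centre to the nearest geometry."""
    geometries = list(geometries)
    if not geometries:
        raise ValueError("empty geometry set")
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = np.full(pts.shape, np.inf)
    for geom in geometries:
        dist = np.minimum(dist, shapely.distance(pts, geom))
    return dist.reshape(grid.shape)


def _horn_gradient(values: np.ndarray, cell_size: float) -> np.ndarray:
    """Magnitude of the Horn 3x3 finite-difference gradient (rise/run).

    Edges use mirrored (reflect) padding.
    """
    z = np.pad(values, 1, mode="reflect")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell_size)
    return np.hypot(dzdx, dzdy)


def complexity(depth: np.ndarray, cell_size: float = 250.0) -> np.ndarray:
    """Terrain complexity: rate of change of slope (second derivative).

    Slope is the Horn 3x3 gradient magnitude of the depth surface; complexity
    applies the same operator to the slope raster. Flat and uniformly sloping
    sea floors both score 0.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.shape[0] < 3 or depth.shape[1] < 3:
        raise ValueError("raster must be at least 3x3")
    slope = _horn_gradient(depth, cell_size)
    return _horn_gradient(slope, cell_size)


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid."""

    grid: Grid
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.layers.items():
            if np.asarray(arr).shape != self.grid.shape:
                raise ValueError(f"layer {name!r} does not match the grid")

    @property
    def names(self):
        return tuple(self.layers)

    def table(self) -> pd.DataFrame:
        """All cells as rows (row-major order), one column per layer."""
        return pd.DataFrame(
            {name: np.asarray(arr).ravel() for name, arr in self.layers.items()}
        )

    def at_cells(self, rows, cols) -> pd.DataFrame:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return pd.DataFrame(
            {name: np.asarray(arr)[rows, cols] for name, arr in self.layers.items()}
        )


def build_stack(grid: Grid, bathymetry, colony_xy, coastline, structure_set) -> CovariateStack:
    """Assemble the seven-layer covariate stack.

    Parameters
    ----------
    bathymetry : array, metres positive down, on ``grid``
    colony_xy : (x, y) of the colony
    coastline : shapely LineString (or any geometry) for the coast
    structure_set : :class:`~sealscape.structures.StructureSet`
    """
    from .structures import LAYER_GROUPS

    bathymetry = np.asarray(bathymetry, dtype=float)
    layers = {
        "depth": bathymetry,
        "complexity": complexity(bathymetry, grid.cell_size),
        "d_colony": distance_raster(grid, [shapely.points(*colony_xy)]),
        "d_coast": distance_raster(grid, [coastline]),
    }
    for layer_name, stypes in LAYER_GROUPS.items():
        geoms = structure_set.geometries(stypes)
        layers[f"d_{layer_name}"] = (
            distance_raster(grid, geoms)
            if geoms
            else np.full(grid.shape, np.nan)
        )
    return CovariateStack(grid=grid, layers=layers)


def extract_covariates(stack: CovariateStack, events) -> pd.DataFrame:
    """Covariate values at foraging-event cells, one row per distinct cell.

    ``events`` is an iterable of objects with ``grid_row``/``grid_col`` (or a
    DataFrame with those columns). Events outside the grid are dropped; the
    number dropped is available as ``df.attrs['n_dropped']``.
    """
    if isinstance(events, pd.DataFrame):
        rows = events["grid_row"].to_numpy()
        cols = events["grid_col"].to_numpy()
    else:
        rows = np.array([e.grid_row for e in events], dtype=int)
        cols = np.array([e.grid_col for e in events], dtype=int)
    inside = stack.grid.contains_cell(rows, cols)
    n_dropped = int((~inside).sum())
    rows, cols = rows[inside], cols[inside]
    uniq = sorted(set(zip(rows.tolist(), cols.tolist())))
    if uniq:
        ur = np.array([r for r, _ in uniq])
        uc = np.array([c for _, c in uniq])
        df = stack.at_cells(ur, uc)
        df.insert(0, "grid_row", ur)
        df.insert(1, "grid_col", uc)
    else:
        df = pd.DataFrame(columns=["grid_row", "grid_col", *stack.names])
    df.attrs["n_dropped"] = n_dropped
    return df


def vif_screen(table: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factors: ``VIF_j = 1 / (1 - R²_j)``.

    Each variable is regressed (with intercept) on all the others. Returns a
    DataFrame with ``vif`` and ``flagged`` (VIF > threshold); a perfectly
    collinear variable reports ``inf``.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    vifs = []
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs.append(np.inf)
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"variable": cols, "vif": vifs})
    out["flagged"] = [v > threshold for v in out["vif"]]
    return out
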