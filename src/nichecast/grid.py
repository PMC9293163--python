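"""Raster grids, climate stacks, occurrence records and point-raster extraction.

All spatial objects share a light-weight :class:`Grid` describing a regular
row-major raster with row 0 at the northern edge.  Cells are half-open
``[x, x+dx) × (y-dy, y]`` so that a point is assigned to a unique cell by
flooring its fractional index; points exactly on a shared edge belong to the
cell with the larger index along x (east) and along y (south), i.e. the floor
rule.  Coordinates are WGS84 longitude/latitude by convention, but any planar
grid works.

Raster I/O supports two formats, chosen by file extension:

``.asc``
    ESRI ASCII grid — plain text, square cells, values stored row 0 first
    (north).  Floats are written with 9 significant digits so float32 data
    round-trips bit-exactly.
``.tif`` / ``.tiff``
    Single- or multi-band float32 TIFF via :mod:`tifffile`, with the
    geotransform and nodata stored in a small JSON sidecar (``<path>.aux.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "ClimateStack",
    "OccurrenceSet",
    "SuitabilityMap",
    "CropCategoryMap",
    "CROP_CATEGORIES",
    "read_raster",
    "read_raster_stack",
    "write_map",
    "write_raster",
    "read_occurrences",
    "extract_values",
]


class GridMismatchError(ValueError):
    """Raised when layers or maps do not share the same grid."""


@dataclass(frozen=True)
class Grid:
    """Regular raster grid; row 0 is the northernmost row.

    Parameters
    ----------
    n_rows, n_cols : int
        Shape of the raster.
    x0, y0 : float
        Coordinates of the *top-left corner* of cell (0, 0).
    dx, dy : float
        Cell size along x (east) and y (south); both positive.
    crs : str
        Label only; no reprojection is performed.
    """

    n_rows: int
    n_cols: int
    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = 1.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) by flooring the fractional index."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.dy).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of cell centers."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y


def _check_same_grid(a: Grid, b: Grid, what: str = "layers") -> None:
    if (a.shape != b.shape or a.x0 != b.x0 or a.y0 != b.y0
            or a.dx != b.dx or a.dy != b.dy):
        raise GridMismatchError(f"{what} do not share the same grid: {a} vs {b}")


@dataclass
class ClimateStack:
    """Named raster layers of (bio)climatic variables on a common grid.

    ``mask`` is True on valid cells and is shared across layers: a cell is
    either valid in every layer or masked everywhere (nodata union).
    """

    grid: Grid
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a ClimateStack needs at least one layer")
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        union_invalid = np.zeros(self.grid.shape, bool)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, float)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}")
            self.layers[name] = arr
            union_invalid |= ~np.isfinite(arr)
        if self.mask is None:
            mask = ~union_invalid
        else:
            mask = np.asarray(self.mask, bool) & ~union_invalid
        self.mask = mask
        for arr in self.layers.values():
            arr[~mask] = np.nan

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of valid cells, row-major order."""
        return np.nonzero(self.mask)

    def values_at(self, rows: np.ndarray, cols: np.ndarray,
                  names: Sequence[str] | None = None) -> np.ndarray:
        """(n_points, n_vars) matrix of layer values at the given cells."""
        names = list(names) if names is not None else self.variable_names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack has no layer(s) {missing}")
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def table(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """All valid cells as a DataFrame (columns = variables, index = (row, col))."""
        rows, cols = self.valid_indices()
        names = list(names) if names is not None else self.variable_names
        df = pd.DataFrame(self.values_at(rows, cols, names), columns=names)
        df.index = pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])
        return df

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        return ClimateStack(self.grid, {n: self.layers[n].copy() for n in names},
                            self.mask.copy())


@dataclass
class OccurrenceSet:
    """Georeferenced occurrence records with a train/validation role flag.

    Records falling on masked cells or outside the grid are *flagged*, never
    silently dropped; flagging happens at extraction time.
    """

    records: pd.DataFrame  # columns: longitude, latitude, source, year, role

    REQUIRED = ("longitude", "latitude")

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks column {col!r}")
        lon = pd.to_numeric(df["longitude"], errors="coerce")
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        bad = ~(np.isfinite(lon) & np.isfinite(lat))
        if bad.any():
            raise ValueError(
                f"non-numeric or non-finite coordinates at rows {list(df.index[bad])}")
        out = ~((lon.abs() <= 360) & (lat.abs() <= 90))
        if out.any():
            raise ValueError(
                f"coordinates out of range at rows {list(df.index[out])}")
        df["longitude"] = lon
        df["latitude"] = lat
        if "source" not in df:
            df["source"] = ""
        if "year" not in df:
            df["year"] = pd.NA
        if "role" not in df:
            df["role"] = "train"
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(float)

    def subset(self, role: str) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["role"] == role].copy())

    def cells(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        return grid.cell_of(self.lon, self.lat)

    @staticmethod
    def from_points(lon: np.ndarray, lat: np.ndarray, source: str = "synthetic",
                    role: str = "train") -> "OccurrenceSet":
        return OccurrenceSet(pd.DataFrame({
            "longitude": lon, "latitude": lat,
            "source": source, "year": pd.NA, "role": role}))


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0, 1] on a grid (NaN on masked cells)."""

    grid: Grid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, float)
        if vals.shape != self.grid.shape:
            raise GridMismatchError("values shape does not match grid")
        if self.mask is None:
            self.mask = np.isfinite(vals)
        else:
            self.mask = np.asarray(self.mask, bool) & np.isfinite(vals)
        vals = vals.copy()
        vals[~self.mask] = np.nan
        valid = vals[self.mask]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")
        self.values = np.clip(vals, 0.0, 1.0)

    def at_points(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        row, col = self.grid.cell_of(lon, lat)
        ok = self.grid.contains(row, col)
        out = np.full(len(np.atleast_1d(row)), np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out


CROP_CATEGORIES = {"suitable": 0, "conditioned": 1, "unsuitable": 2, "nodata": -1}
_CROP_NAMES = {v: k for k, v in CROP_CATEGORIES.items()}


@dataclass
class CropCategoryMap:
    """Categorical crop-suitability raster: suitable / conditioned / unsuitable."""

    grid: Grid
    categories: np.ndarray  # int codes per CROP_CATEGORIES

    def __post_init__(self) -> None:
        cats = np.asarray(self.categories)
        if cats.shape != self.grid.shape:
            raise GridMismatchError("categories shape does not match grid")
        cats = cats.astype(int)
        allowed = set(CROP_CATEGORIES.values())
        present = set(np.unique(cats).tolist())
        if not present <= allowed:
            raise ValueError(f"unknown category codes {sorted(present - allowed)}")
        self.categories = cats

    @property
    def mask(self) -> np.ndarray:
        return self.categories != CROP_CATEGORIES["nodata"]

    def category_names(self) -> np.ndarray:
        return np.vectorize(_CROP_NAMES.get)(self.categories)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASC_NODATA = -9999.0


def _write_asc(path: Path, arr: np.ndarray, grid: Grid, nodata: float = _ASC_NODATA) -> None:
    if not np.isclose(grid.dx, grid.dy):
        raise ValueError("ESRI ASCII grids require square cells; use .tif instead")
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {grid.x0!r}\nyllcorner {grid.y0 - grid.n_rows * grid.dy!r}\n"
              f"cellsize {grid.dx!r}\nNODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.9g")


def _read_asc(path: Path) -> tuple[np.ndarray, Grid]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh, dtype=np.float64)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    arr = arr.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _ASC_NODATA)
    arr[arr == nodata] = np.nan
    cell = header["cellsize"]
    grid = Grid(n_rows, n_cols, x0=header["xllcorner"],
                y0=header["yllcorner"] + n_rows * cell, dx=cell, dy=cell)
    return arr, grid


def _write_tif(path: Path, arr: np.ndarray, grid: Grid, nodata: float = _ASC_NODATA) -> None:
    import tifffile

    out = np.where(np.isfinite(arr), arr, nodata).astype(np.float32)
    tifffile.imwrite(path, out)
    sidecar = {"x0": grid.x0, "y0": grid.y0, "dx": grid.dx, "dy": grid.dy,
               "crs": grid.crs, "nodata": nodata}
    Path(str(path) + ".aux.json").write_text(json.dumps(sidecar))


def _read_tif(path: Path) -> tuple[np.ndarray, Grid]:
    import tifffile

    arr = np.asarray(tifffile.imread(path), float)
    aux = Path(str(path) + ".aux.json")
    meta = json.loads(aux.read_text()) if aux.exists() else {}
    nodata = meta.get("nodata", _ASC_NODATA)
    arr[arr == nodata] = np.nan
    grid = Grid(arr.shape[0], arr.shape[1], x0=meta.get("x0", 0.0),
                y0=meta.get("y0", 0.0), dx=meta.get("dx", 1.0),
                dy=meta.get("dy", 1.0), crs=meta.get("crs", "EPSG:4326"))
    return arr, grid


def write_raster(arr: np.ndarray, grid: Grid, path: str | Path) -> Path:
    """Write a single float layer; format chosen by extension (.asc or .tif)."""
    path = Path(path)
    arr32 = np.asarray(arr, np.float32).astype(np.float64)
    if path.suffix.lower() == ".asc":
        _write_asc(path, arr32, grid)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tif(path, arr32, grid)
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r}")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid]:
    path = Path(path)
    if path.suffix.lower() == ".asc":
        return _read_asc(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tif(path)
    raise ValueError(f"unsupported raster extension {path.suffix!r}")


def read_raster_stack(paths: Sequence[str | Path],
                      names: Sequence[str]) -> ClimateStack:
    """Read one raster per variable and stack them with a unified nodata mask."""
    if len(paths) < 1:
        raise ValueError("need at least one raster")
    if len(paths) != len(names):
        raise ValueError("paths and names differ in length")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate variable names in {list(names)}")
    layers: dict[str, np.ndarray] = {}
    grid: Grid | None = None
    for path, name in zip(paths, names):
        arr, g = read_raster(path)
        if grid is None:
            grid = g
        else:
            _check_same_grid(grid, g, what=f"raster {path}")
        layers[name] = arr
    assert grid is not None
    return ClimateStack(grid, layers)


def write_map(obj: SuitabilityMap | CropCategoryMap, path: str | Path) -> Path:
    """Write a suitability or crop-category map (float32 / integer codes)."""
    if isinstance(obj, SuitabilityMap):
        return write_raster(obj.values, obj.grid, path)
    if isinstance(obj, CropCategoryMap):
        arr = np.where(obj.mask, obj.categories.astype(float), np.nan)
        return write_raster(arr, obj.grid, path)
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_suitability(path: str | Path) -> SuitabilityMap:
    arr, grid = read_raster(path)
    return SuitabilityMap(grid, arr)


def read_crop_map(path: str | Path) -> CropCategoryMap:
    arr, grid = read_raster(path)
    cats = np.where(np.isfinite(arr), arr, CROP_CATEGORIES["nodata"])
    return CropCategoryMap(grid, np.rint(cats).astype(int))


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path, role: str = "train") -> OccurrenceSet:
    """Load an occurrence CSV (``longitude,latitude[,source,year]``).

    Every row becomes one record with the given role; the record count is the
    table length — discrepancies between a stated total and the sum of roles
    are the caller's to reconcile, never silently fixed here.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    df["role"] = role
    return OccurrenceSet(df)


def extract_values(stack: ClimateStack, points: OccurrenceSet,
                   names: Sequence[str] | None = None,
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Point-in-cell extraction of stack values at occurrence locations.

    Returns ``(values, missing)`` where *values* has one row per point (NaN
    rows for points off-grid or on masked cells) and *missing* lists the
    indices of those flagged points.
    """
    names = list(names) if names is not None else stack.variable_names
    row, col = points.cells(stack.grid)
    inside = stack.grid.contains(row, col)
    valid = inside.copy()
    valid[inside] &= stack.mask[row[inside], col[inside]]
    if not valid.any():
        raise ValueError("no occurrence point falls on a valid grid cell")
    out = np.full((len(points), len(names)), np.nan)
    out[valid] = stack.values_at(row[valid], col[valid], names)
    missing = np.nonzero(~valid)[0]
    return pd.DataFrame(out, columns=names), missing


def presence_cells(stack: ClimateStack, points: OccurrenceSet,
                   thin: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Valid cells occupied by occurrence points.

    With ``thin=True`` (standard SDM practice) duplicate records in one cell
    collapse to a single presence cell.
    """
    row, col = points.cells(stack.grid)
    inside = stack.grid.contains(row, col)
    row, col = row[inside], col[inside]
    ok = stack.mask[row, col]
    row, col = row[ok], col[ok]
    if row.size == 0:
        raise ValueError("no occurrence point falls on a valid grid cell")
    if thin:
        flat = np.unique(row * stack.grid.n_cols + col)
        row, col = flat // stack.grid.n_cols, flat % stack.grid.n_cols
    return row, col
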