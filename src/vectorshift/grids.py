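"""Lightweight geographic raster grids.

A :class:`GridSpec` describes a regular latitude/longitude grid (WGS84) by
its origin (the *upper-left corner* of the upper-left cell), square cell size
in degrees, and shape. A :class:`PredictorStack` is an ordered mapping of
layer name -> 2-D array on one shared grid: the in-memory "raster stack" used
throughout the package for bioclimatic variables, land-use fractions and any
other gridded predictor.

Layers are read and written as plain-text ESRI ASCII grids (``.asc``), which
round-trips through any standard GIS tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "PredictorStack",
    "cell_area_km2",
    "resample_to_grid",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid in degrees (WGS84).

    ``origin_lon``/``origin_lat`` locate the upper-left corner of the
    upper-left cell; rows run north to south, columns west to east.
    """

    n_rows: int
    n_cols: int
    cell_size_deg: float
    origin_lon: float = 0.0
    origin_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        return (
            self.origin_lon + (col + 0.5) * self.cell_size_deg,
            self.origin_lat - (row + 0.5) * self.cell_size_deg,
        )

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing the given points.

        Points on a cell edge belong to the cell below/right of the edge,
        except on the outer south/east boundary where they are clamped in.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size_deg).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size_deg).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col


def cell_area_km2(grid: GridSpec, row: int | np.ndarray) -> float | np.ndarray:
    """Area of cells in the given row(s), spherical Earth (km**2).

    The area of a lon/lat rectangle on a sphere is
    ``R**2 * dlam * (sin(phi_top) - sin(phi_bottom))`` with ``dlam`` the
    longitudinal width in radians, so it depends on latitude only.
    """
    row = np.asarray(row)
    lat_top_deg = grid.origin_lat - row * grid.cell_size_deg
    lat_top = np.deg2rad(lat_top_deg)
    lat_bot = np.deg2rad(lat_top_deg - grid.cell_size_deg)
    dlam = math.radians(grid.cell_size_deg)
    area = EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    return float(area) if area.ndim == 0 else area


class PredictorStack:
    """Named 2-D float layers sharing one :class:`GridSpec`."""

    def __init__(self, grid: GridSpec, layers: Mapping[str, np.ndarray] | None = None):
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        if layers:
            for name, arr in layers.items():
                self[name] = arr

    def __setitem__(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
            )
        self._layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def values_at(
        self, lon: np.ndarray, lat: np.ndarray, names: Iterable[str] | None = None
    ) -> np.ndarray:
        """Extract layer values at point locations (n_points, n_layers)."""
        names = list(names) if names is not None else self.names
        row, col = self.grid.cell_index(np.asarray(lon), np.asarray(lat))
        return np.column_stack([self._layers[n][row, col] for n in names])

    def as_matrix(self, names: Iterable[str] | None = None) -> np.ndarray:
        """All cells flattened row-major into (n_cells, n_layers)."""
        names = list(names) if names is not None else self.names
        return np.column_stack([self._layers[n].ravel() for n in names])

    def copy(self) -> "PredictorStack":
        return PredictorStack(self.grid, {k: v.copy() for k, v in self._layers.items()})

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self._layers.items():
            write_ascii_grid(directory / f"{name}.asc", self.grid, arr)

    @classmethod
    def load(cls, directory: str | Path) -> "PredictorStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        stack = None
        for p in paths:
            grid, arr = read_ascii_grid(p)
            if stack is None:
                stack = cls(grid)
            stack[p.stem] = arr
        return stack


def write_ascii_grid(path: str | Path, grid: GridSpec, arr: np.ndarray, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (plain text)."""
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size_deg}\n"
        f"cellsize {grid.cell_size_deg}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size_deg=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
    )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return grid, data


def resample_to_grid(
    stack: PredictorStack,
    target: GridSpec,
    method: Literal["nearest", "bilinear"] = "bilinear",
) -> PredictorStack:
    """Resample every layer onto ``target``.

    ``bilinear`` for continuous fields, ``nearest`` for categorical or
    fraction layers. Values are interpolated between source cell centers;
    target centers outside the source center hull take the nearest source
    value (constant extrapolation), and NaN source cells propagate.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    src = stack.grid
    src_right = src.origin_lon + src.n_cols * src.cell_size_deg
    src_bottom = src.origin_lat - src.n_rows * src.cell_size_deg
    tgt_right = target.origin_lon + target.n_cols * target.cell_size_deg
    tgt_bottom = target.origin_lat - target.n_rows * target.cell_size_deg
    if (
        target.origin_lon >= src_right
        or tgt_right <= src.origin_lon
        or target.origin_lat <= src_bottom
        or tgt_bottom >= src.origin_lat
    ):
        raise ValueError("source and target grids do not overlap")

    # interpolate on (lat descending -> use row coordinate, lon ascending)
    src_lat = src.lat_centers()[::-1]  # ascending for interpolator
    src_lon = src.lon_centers()
    tgt_lon, tgt_lat = np.meshgrid(target.lon_centers(), target.lat_centers())
    pts = np.column_stack(
        [
            np.clip(tgt_lat.ravel(), src_lat[0], src_lat[-1]),
            np.clip(tgt_lon.ravel(), src_lon[0], src_lon[-1]),
        ]
    )
    out = PredictorStack(target)
    kind = "linear" if method == "bilinear" else "nearest"
    for name in stack.names:
        arr = stack[name][::-1, :]  # flip rows to match ascending lat
        interp = RegularGridInterpolator(
            (src_lat, src_lon), arr, method=kind, bounds_error=False, fill_value=None
        )
        out[name] = interp(pts).reshape(target.shape)
    return out
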