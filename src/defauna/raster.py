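"""Gridded spatial data model and plain-text raster I/O.

A :class:`RasterGrid` is a single-band, square-celled, row-major grid with
row 0 at the northern edge, a sentinel nodata value and a free-text CRS
label.  All distances and areas in this package are planar: geographic
inputs must be projected to a metric CRS before use.

Files are read and written in the ESRI ASCII grid format (``.asc``) — a
plain-text, single-band raster interchange format understood by every
mainstream GIS — with the CRS label in a ``.prj`` sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "EnvStack", "read_raster", "write_raster", "slope_mask"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Georeferenced 2-D grid with nodata sentinel.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    origin_x, origin_y
        Map coordinates of the *top-left corner* of the grid.
    cell_size
        Positive edge length of the (square) cells, in map units.
    nodata
        Sentinel marking invalid cells.
    crs_label
        Free-text CRS identifier; two rasters interoperate only if the
        labels match.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata and finite."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of all cell centers, shape = grid shape."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing map point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def aligned_with(self, other: "RasterGrid") -> bool:
        """Exact-match alignment: origin, cell size, shape, CRS."""
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, rel_tol=0, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=0, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
            and self.crs_label == other.crs_label
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New raster with this grid's geometry and the given values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "RasterGrid":
        return self.like(self.values.copy())

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class EnvStack:
    """Named stack of aligned environmental layers."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        rasters = list(self.layers.values())
        for r in rasters[1:]:
            if not r.aligned_with(rasters[0]):
                raise ValueError("all layers in an EnvStack must be aligned")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def subset(self, names) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})

    def common_valid_mask(self) -> np.ndarray:
        mask = np.ones(self.template.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid_mask()
        return mask


# -- file I/O -----------------------------------------------------------


def write_raster(raster: RasterGrid, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid plus ``.prj`` CRS sidecar.

    Values are written with ``repr``-level precision so that a
    write→read round trip is bit-exact.
    """
    path = Path(path)
    nrows, ncols = raster.shape
    yll = raster.origin_y - nrows * raster.cell_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(raster.origin_x)!r}\n"
        f"yllcorner {float(yll)!r}\n"
        f"cellsize {float(raster.cell_size)!r}\n"
        f"NODATA_value {float(raster.nodata)!r}\n"
    )
    vals = np.where(raster.valid_mask(), raster.values, raster.nodata)
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
    path.write_text(header + body + "\n")
    path.with_suffix(".prj").write_text(raster.crs_label + "\n")
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band ESRI ASCII grid (with optional ``.prj`` sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "dx", "dy", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "dx" in header or "dy" in header:
        raise ValueError(f"{path}: non-square cells are not supported")
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows}x{ncols} values, got {data.size} "
            "(multi-band rasters are not supported)"
        )
    data = data.reshape(nrows, ncols)
    prj = path.with_suffix(".prj")
    crs_label = prj.read_text().strip() if prj.exists() else "local"
    return RasterGrid(
        values=data,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        crs_label=crs_label,
    )


# -- terrain ------------------------------------------------------------


def slope_mask(dem: RasterGrid, threshold_deg: float = 45.0) -> RasterGrid:
    """Binary mask of cells with terrain slope strictly above a threshold.

    Slope is computed with Horn's 8-neighbour finite-difference kernel
    (the standard GIS slope estimator); border cells use replicated
    edges.  The DEM must be in the same linear units as its cell size
    (typically metres) for the angle to be meaningful.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("slope requires a DEM of at least 3x3 cells")
    z = np.pad(dem.values, 1, mode="edge")
    c = dem.cell_size
    # Horn kernel: weights 1-2-1 across the 3 neighbours on each side
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * c)
    dzdy = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8 * c)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = (slope > threshold_deg).astype(float)
    out[~dem.valid_mask()] = dem.nodata
    return dem.like(out)
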