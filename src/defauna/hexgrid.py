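"""Vector regions, hexagonal analysis grids and zonal statistics.

The analysis grid is a tiling of congruent flat-top regular hexagons
(area ``(3*sqrt(3)/2) * edge**2``); with the 5-km edge used for the
landscape analysis each hexcell covers 64.95 km².  Hexcells are ordered
row-major from the north-west corner for reproducibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union

from .raster import RasterGrid

__all__ = [
    "VectorRegion",
    "HexGrid",
    "hexagon_area",
    "build_hexgrid",
    "zonal_stat",
    "read_region",
    "write_region",
]

SQRT3 = math.sqrt(3.0)


@dataclass
class VectorRegion:
    """A set of polygons with attributes (region boundary, protected areas)."""

    polygons: list[tuple[str, Polygon, dict]] = field(default_factory=list)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        for pid, poly, _ in self.polygons:
            if not poly.is_valid:
                raise ValueError(f"polygon {pid!r} is invalid (self-intersecting?)")

    @property
    def union(self):
        if not self.polygons:
            raise ValueError("empty region")
        return unary_union([p for _, p, _ in self.polygons])

    @property
    def is_empty(self) -> bool:
        return not self.polygons or all(p.is_empty for _, p, _ in self.polygons)

    def with_attr(self, key: str, value) -> "VectorRegion":
        keep = [(i, p, a) for i, p, a in self.polygons if a.get(key) == value]
        return VectorRegion(keep, self.crs_label)

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, crs_label="local") -> "VectorRegion":
        poly = Polygon(
            [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax), (xmin, ymin)]
        )
        return cls([("region", poly, {})], crs_label)


def read_region(path: str | Path, crs_label: str | None = None) -> VectorRegion:
    """Load polygons from a GeoJSON FeatureCollection.

    The CRS label round-trips through a top-level ``crs_label`` member
    (GeoJSON itself is CRS-agnostic); an explicit argument overrides it.
    """
    gj = json.loads(Path(path).read_text())
    if crs_label is None:
        crs_label = gj.get("crs_label", "local")
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for k, f in enumerate(feats):
        geom = shape(f["geometry"])
        props = dict(f.get("properties") or {})
        pid = str(props.get("id", k))
        if geom.geom_type == "MultiPolygon":
            for j, g in enumerate(geom.geoms):
                polys.append((f"{pid}.{j}", g, props))
        else:
            polys.append((pid, geom, props))
    return VectorRegion(polys, crs_label)


def write_region(region: VectorRegion, path: str | Path) -> Path:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"id": pid, **attrs},
        }
        for pid, poly, attrs in region.polygons
    ]
    Path(path).write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "crs_label": region.crs_label,
                "features": feats,
            }
        )
    )
    return Path(path)


def hexagon_area(edge_km: float) -> float:
    """Area of a regular hexagon with the given edge length."""
    return 1.5 * SQRT3 * edge_km**2


@dataclass
class HexGrid:
    """Flat-top regular hexagon tiling clipped to a region.

    ``cells`` holds ``(cell_id, center_x, center_y, vertices)`` in
    deterministic row-major order (north to south, west to east).
    """

    edge: float
    cells: list[tuple[int, float, float, np.ndarray]]
    crs_label: str = "local"

    @property
    def cell_area(self) -> float:
        return hexagon_area(self.edge)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(cx, cy) for _, cx, cy, _ in self.cells])

    def polygons(self) -> list[Polygon]:
        return [Polygon(v) for _, _, _, v in self.cells]

    def to_geojson(self, path: str | Path) -> Path:
        region = VectorRegion(
            [(str(cid), Polygon(v), {"cell_id": cid}) for cid, _, _, v in self.cells],
            self.crs_label,
        )
        return write_region(region, path)


def _hex_vertices(cx: float, cy: float, edge: float) -> np.ndarray:
    ang = np.arange(6) * (math.pi / 3.0)  # flat-top: vertex at angle 0
    return np.column_stack([cx + edge * np.cos(ang), cy + edge * np.sin(ang)])


def build_hexgrid(region: VectorRegion, edge_km: float) -> HexGrid:
    """All hexagons of the flat-top tiling that intersect the region.

    The tiling is anchored at the top-left corner of the region's
    bounding box; centers advance 1.5*edge horizontally and sqrt(3)*edge
    vertically, with odd columns shifted half a row down.
    """
    if edge_km <= 0:
        raise ValueError("edge_km must be positive")
    if region.is_empty:
        raise ValueError("empty region")
    geom = region.union
    xmin, ymin, xmax, ymax = geom.bounds
    dx = 1.5 * edge_km
    dy = SQRT3 * edge_km
    ncol = int(math.ceil((xmax - xmin) / dx)) + 2
    nrow = int(math.ceil((ymax - ymin) / dy)) + 2
    cand = []
    for col in range(-1, ncol + 1):
        cx = xmin + col * dx
        off = 0.5 * dy if col % 2 else 0.0
        for row in range(-1, nrow + 1):
            cy = ymax - row * dy - off
            cand.append((cx, cy))
    keep = []
    for cx, cy in cand:
        verts = _hex_vertices(cx, cy, edge_km)
        poly = Polygon(verts)
        if poly.intersects(geom):
            keep.append((cx, cy, verts))
    # row-major: north to south, then west to east; round to kill FP jitter
    keep.sort(key=lambda t: (-round(t[1] / (0.25 * dy)), round(t[0] / (0.25 * dx))))
    cells = [(i, cx, cy, verts) for i, (cx, cy, verts) in enumerate(keep)]
    return HexGrid(edge=edge_km, cells=cells, crs_label=region.crs_label)


def zonal_stat(
    raster: RasterGrid, grid: HexGrid, stat: str = "mean"
) -> dict[int, float]:
    """Per-hexcell statistic over the raster cells whose centers it contains.

    Nodata raster cells are excluded; hexcells containing no valid cell
    center are absent from the returned mapping.
    """
    if stat not in {"mean", "sum", "max"}:
        raise ValueError(f"unsupported stat {stat!r}")
    if raster.crs_label != grid.crs_label:
        raise ValueError(
            f"CRS mismatch: raster {raster.crs_label!r} vs grid {grid.crs_label!r}"
        )
    mask = raster.valid_mask()
    if not mask.any() or grid.n_cells == 0:
        return {}
    gx, gy = raster.cell_centers()
    px, py = gx[mask], gy[mask]
    vals = raster.values[mask]
    # nearest hex center is the true tiling membership (hexagonal Voronoi);
    # confirm with a covers() test so points outside the clipped grid drop out
    tree = cKDTree(grid.centers)
    dist, idx = tree.query(np.column_stack([px, py]))
    polys = shapely.polygons([v for _, _, _, v in grid.cells])
    covered = shapely.intersects(polys[idx], shapely.points(px, py))
    out: dict[int, float] = {}
    idx, vals = idx[covered], vals[covered]
    order = np.argsort(idx, kind="stable")
    idx, vals = idx[order], vals[order]
    bounds = np.searchsorted(idx, np.arange(grid.n_cells + 1))
    for cid in range(grid.n_cells):
        lo, hi = bounds[cid], bounds[cid + 1]
        if lo == hi:
            continue
        v = vals[lo:hi]
        out[cid] = {"mean": v.mean(), "sum": v.sum(), "max": v.max()}[stat]
    return out


def rasterize_region(region: VectorRegion, template: RasterGrid) -> RasterGrid:
    """Binary raster: 1 where the template cell center lies in the region."""
    geom = region.union
    gx, gy = template.cell_centers()
    pts = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.intersects(geom, pts).reshape(template.shape)
    return template.like(inside.astype(float))
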