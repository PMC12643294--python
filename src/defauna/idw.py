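"""Inverse-distance-weighted contemporary distribution surfaces.

Contemporary assemblage data are point observations (site × species
incidence); IDW turns them into rasters: the value at a grid cell is the
weighted mean of the site values with weights ``d^(-p)``.  The
interpolant is exact at the sample points, bounded by the data range,
and continuous away from the samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "IDWConfig",
    "idw_interpolate",
    "contemporary_richness_surface",
    "contemporary_species_surface",
    "load_assemblages",
    "assemblage_summary",
]

SITE_COLUMNS = ["site_id", "x", "y", "protection"]
PROTECTION_LEVELS = ("none", "sustainable", "strict")


@dataclass
class IDWConfig:
    power: float = 2.0
    k_nearest: int | None = None  # None = all points
    exact_at_samples: bool = True

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("IDW power must be positive")
        if self.k_nearest is not None and self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1 when set")


def idw_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    template: RasterGrid,
    config: IDWConfig | None = None,
) -> RasterGrid:
    """IDW surface of scattered values on the template grid.

    ``value(cell) = Σ w_i v_i / Σ w_i`` with ``w_i = d_i^(-p)``.  A cell
    whose center coincides with a sample point (within 1e-9 cell sizes)
    takes that sample's value exactly.  Duplicate points with
    conflicting values are rejected.
    """
    config = config or IDWConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(values, dtype=float).ravel()
    if pts.shape[0] == 0:
        raise ValueError("IDW requires at least one point")
    if pts.shape[0] != vals.size:
        raise ValueError("points and values length mismatch")
    eps = 1e-9 * template.cell_size
    # reject coincident duplicates with conflicting values
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    sp, sv = pts[order], vals[order]
    same = np.all(np.abs(np.diff(sp, axis=0)) < eps, axis=1)
    if np.any(same & (np.abs(np.diff(sv)) > 0)):
        raise ValueError("duplicate points with conflicting values")

    gx, gy = template.cell_centers()
    qx, qy = gx.ravel(), gy.ravel()
    d = np.hypot(qx[:, None] - pts[None, :, 0], qy[:, None] - pts[None, :, 1])
    out = np.empty(qx.size)
    at_sample = d.min(axis=1) < eps
    if config.exact_at_samples and at_sample.any():
        out[at_sample] = vals[d[at_sample].argmin(axis=1)]
    with np.errstate(divide="ignore"):
        w = d ** (-config.power)
    if config.k_nearest is not None and config.k_nearest < pts.shape[0]:
        cut = np.argsort(d, axis=1)[:, config.k_nearest :]
        np.put_along_axis(w, cut, 0.0, axis=1)
    free = ~at_sample if config.exact_at_samples else np.ones(qx.size, bool)
    out[free] = (w[free] @ vals) / w[free].sum(axis=1)
    result = out.reshape(template.shape)
    result[~template.valid_mask()] = template.nodata
    return template.like(result)


def load_assemblages(path) -> pd.DataFrame:
    """Read and validate a site × species assemblage CSV.

    Schema: ``site_id, x, y, protection`` then one 0/1 column per
    species.  Coordinates must be unique per site and incidence binary.
    """
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assemblage table missing columns {missing}")
    bad = set(df["protection"]) - set(PROTECTION_LEVELS)
    if bad:
        raise ValueError(f"unknown protection categories {sorted(bad)}")
    if df.duplicated(subset=["x", "y"]).any():
        raise ValueError("duplicate site coordinates")
    sp_cols = species_columns(df)
    if not sp_cols:
        raise ValueError("no species incidence columns found")
    inc = df[sp_cols].to_numpy()
    if not np.isin(inc, (0, 1)).all():
        raise ValueError("species incidence must be binary")
    return df


def species_columns(assemblages: pd.DataFrame) -> list[str]:
    return [c for c in assemblages.columns if c not in SITE_COLUMNS]


def site_richness(assemblages: pd.DataFrame) -> pd.Series:
    s = assemblages[species_columns(assemblages)].sum(axis=1)
    s.index = assemblages["site_id"]
    return s


def assemblage_summary(assemblages: pd.DataFrame) -> dict:
    """Richness summary of an assemblage table (mean, SD, range, pool size)."""
    rich = site_richness(assemblages)
    sp = species_columns(assemblages)
    present = [c for c in sp if assemblages[c].sum() > 0]
    return {
        "n_sites": int(len(assemblages)),
        "mean_richness": float(rich.mean()),
        "sd_richness": float(rich.std(ddof=1)),
        "min_richness": int(rich.min()),
        "max_richness": int(rich.max()),
        "n_species": int(len(present)),
    }


def contemporary_richness_surface(
    assemblages: pd.DataFrame,
    template: RasterGrid,
    config: IDWConfig | None = None,
) -> RasterGrid:
    """IDW of per-site contemporary richness over the region."""
    pts = assemblages[["x", "y"]].to_numpy()
    rich = site_richness(assemblages).to_numpy()
    return idw_interpolate(pts, rich, template, config)


def contemporary_species_surface(
    assemblages: pd.DataFrame,
    species_id: str,
    template: RasterGrid,
    config: IDWConfig | None = None,
    cutoff: float = 0.5,
) -> RasterGrid:
    """Binary contemporary range: IDW of 0/1 incidence, thresholded at ≥ cutoff."""
    if species_id not in assemblages.columns:
        raise KeyError(f"species {species_id!r} not in assemblage table")
    pts = assemblages[["x", "y"]].to_numpy()
    inc = assemblages[species_id].to_numpy(dtype=float)
    surface = idw_interpolate(pts, inc, template, config)
    mask = surface.valid_mask()
    out = np.where(mask, (surface.values >= cutoff).astype(float), surface.nodata)
    return surface.like(out)
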