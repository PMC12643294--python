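"""Defaunation, downsizing, range-loss and protection-status metrics.

Defaunation is the historical-minus-contemporary difference in species
richness, mapped per cell and summarised per hexcell; downsizing is the
loss of aggregate/mean body mass of an assemblage between the two
periods; range loss extrapolates per-species assemblage occupancy to
area; the protection comparison is a Tukey-Kramer HSD on biomass
retention across protection categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hexgrid import HexGrid, zonal_stat
from .idw import species_columns
from .raster import RasterGrid

__all__ = [
    "DefaunationRaster",
    "defaunation_raster",
    "defaunation_by_hexcell",
    "loss_band_summary",
    "species_range_loss",
    "historical_composition",
    "downsizing",
    "protection_comparison",
]

log = logging.getLogger(__name__)


@dataclass
class DefaunationRaster:
    difference: RasterGrid  # D = historical - contemporary richness
    percent_loss: RasterGrid  # 100*D/historical where historical > 0


def defaunation_raster(hist: RasterGrid, cont: RasterGrid) -> DefaunationRaster:
    """D = historical − contemporary richness, with percent loss.

    Percent loss is only defined where historical richness is positive;
    local gains (negative D) are preserved, not clipped.
    """
    if not hist.aligned_with(cont):
        raise ValueError("historical and contemporary rasters are not aligned")
    valid = hist.valid_mask() & cont.valid_mask()
    d = np.where(valid, hist.values - cont.values, hist.nodata)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            valid & (hist.values > 0),
            100.0 * (hist.values - cont.values) / hist.values,
            hist.nodata,
        )
    return DefaunationRaster(hist.like(d), hist.like(pct))


def defaunation_by_hexcell(
    d: RasterGrid,
    grid: HexGrid,
    covariates: dict[str, RasterGrid],
    covariate_stats: dict[str, str] | None = None,
    historical: RasterGrid | None = None,
    min_historical_richness: float | None = None,
) -> pd.DataFrame:
    """Zonal mean of defaunation and of each driver covariate per hexcell.

    ``covariate_stats`` may override the zonal statistic per covariate
    (e.g. ``{"pas": "sum"}`` for protected area extent); default mean.
    Hexcells with no valid response or a missing covariate are dropped
    (count logged).  When ``historical`` and ``min_historical_richness``
    are given, the analysis is confined to hexcells whose zonal mean
    historical richness reaches the threshold — the driver regression
    concerns the part of the landscape that supports the fauna, as a
    biome-wide analysis is confined to the biome.
    """
    covariate_stats = covariate_stats or {}
    response = zonal_stat(d, grid, "mean")
    table = {"defaunation": response}
    for name, rast in covariates.items():
        table[name] = zonal_stat(rast, grid, covariate_stats.get(name, "mean"))
    df = pd.DataFrame(table)
    df.index.name = "cell_id"
    n_before = grid.n_cells
    df = df.dropna()
    if historical is not None and min_historical_richness is not None:
        hz = zonal_stat(historical, grid, "mean")
        keep = [cid for cid in df.index if hz.get(cid, 0.0) >= min_historical_richness]
        df = df.loc[keep]
    dropped = n_before - len(df)
    if dropped:
        log.info("defaunation_by_hexcell: dropped %d hexcell(s)", dropped)
    return df.reset_index()


DEFAULT_BANDS = (
    ("over_50", 50.0, 100.0 + 1e-12, "right_closed"),
    ("20_to_49", 20.0, 50.0, "left_closed"),
    ("under_20", 0.0, 20.0, "left_closed"),
)


def loss_band_summary(
    percent: RasterGrid, include_gains: bool = True
) -> dict[str, float]:
    """Fraction of valid area in each percent-loss band.

    Bands follow the reporting convention: losses over 50% ((50, 100]),
    moderate losses ([20, 50)), light losses ([0, 20)), and gains
    (negative percent loss) reported separately.  Fractions over the
    exhaustive bands sum to 1.
    """
    v = percent.valid_values()
    if v.size == 0:
        raise ValueError("percent-loss raster has no valid cells")
    out = {
        "gains": float((v < 0).mean()),
        "under_20": float(((v >= 0) & (v < 20)).mean()),
        "20_to_49": float(((v >= 20) & (v < 50)).mean()),
        "over_50": float((v >= 50).mean()),
    }
    if not include_gains:
        out.pop("gains")
    return out


def historical_composition(
    binary_maps: dict[str, RasterGrid], sites: pd.DataFrame
) -> pd.DataFrame:
    """Historical site × species incidence read off the binary SDM maps.

    A species is historically present at a site iff its binary map is 1
    in the raster cell containing the site (no buffer).
    """
    first = next(iter(binary_maps.values()))
    rows, cols = first.index_of(sites["x"].to_numpy(), sites["y"].to_numpy())
    data = {}
    for sp, bm in binary_maps.items():
        data[sp] = (bm.values[rows, cols] > 0).astype(int)
    out = sites[[c for c in ("site_id", "x", "y", "protection") if c in sites]].copy()
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(data)], axis=1)


@dataclass
class SpeciesRangeLoss:
    species_id: str
    n_assemblages_predicted: int
    n_assemblages_occupied: int
    loss_fraction: float | None
    historical_area_km2: float
    lost_area_km2: float | None
    n_commission: int  # occupied at sites not historically predicted
    assessable: bool


def species_range_loss(
    binary_maps: dict[str, RasterGrid],
    assemblages: pd.DataFrame,
    cell_area_km2: float | None = None,
) -> pd.DataFrame:
    """Per-species range loss from assemblage occupancy, scaled to area.

    ``loss_fraction = 1 − occupied/predicted`` over the assemblages where
    the species is historically predicted; the fraction is extrapolated
    to the species' historical range area (valid-cell count × cell
    area).  Species predicted at no assemblage are flagged not
    assessable and excluded from summaries.
    """
    hist = historical_composition(binary_maps, assemblages)
    records = []
    for sp, bm in binary_maps.items():
        if sp not in assemblages.columns:
            continue
        pred = hist[sp].to_numpy() > 0
        occ = assemblages[sp].to_numpy() > 0
        n_pred = int(pred.sum())
        n_occ = int((pred & occ).sum())
        n_comm = int((~pred & occ).sum())
        area = float(
            (bm.values[bm.valid_mask()] > 0).sum()
            * (cell_area_km2 if cell_area_km2 is not None else bm.cell_area)
        )
        if n_pred == 0:
            records.append(
                SpeciesRangeLoss(sp, 0, 0, None, area, None, n_comm, False)
            )
            continue
        loss = 1.0 - n_occ / n_pred
        records.append(
            SpeciesRangeLoss(sp, n_pred, n_occ, loss, area, loss * area, n_comm, True)
        )
    return pd.DataFrame([r.__dict__ for r in records])


def augment_historical(
    historical: pd.DataFrame, assemblages: pd.DataFrame
) -> pd.DataFrame:
    """Union of modelled historical and observed contemporary composition.

    A species observed at a site today was necessarily present there
    historically, so the observation overrides a model omission; this
    removes spurious biomass "gains" caused purely by model error.
    """
    sp_cols = [c for c in species_columns(assemblages) if c in historical.columns]
    hist = historical.set_index("site_id")
    out = historical.copy().set_index("site_id")
    obs = assemblages.set_index("site_id")
    common = [s for s in obs.index if s in hist.index]
    out.loc[common, sp_cols] = np.maximum(
        hist.loc[common, sp_cols].to_numpy(), obs.loc[common, sp_cols].to_numpy()
    )
    return out.reset_index()


def downsizing(
    assemblages: pd.DataFrame,
    historical: pd.DataFrame,
    mass_kg: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Per-site aggregate/mean body mass change between periods.

    ``mass_kg`` maps species_id → adult body mass in kg.  Returns one
    record per site (aggregate and mean masses for both periods, the
    retained biomass fraction and the species-loss count) plus regional
    summaries including total biomass loss.
    """
    sp_cols = species_columns(assemblages)
    missing = [s for s in sp_cols if s not in mass_kg.index]
    if missing:
        raise KeyError(f"species without a body mass: {missing}")
    m = mass_kg.loc[sp_cols].to_numpy(dtype=float)
    hist = historical.set_index("site_id").loc[
        assemblages["site_id"], sp_cols
    ].to_numpy(dtype=float)
    cont = assemblages[sp_cols].to_numpy(dtype=float)
    agg_h = hist @ m
    agg_c = cont @ m
    rich_h = hist.sum(axis=1)
    rich_c = cont.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = np.where(rich_h > 0, agg_h / np.maximum(rich_h, 1), np.nan)
        mean_c = np.where(rich_c > 0, agg_c / np.maximum(rich_c, 1), np.nan)
        retained = np.where(agg_h > 0, agg_c / agg_h, np.nan)
    records = pd.DataFrame(
        {
            "site_id": assemblages["site_id"],
            "protection": assemblages["protection"],
            "aggregate_mass_hist_kg": agg_h,
            "aggregate_mass_cont_kg": agg_c,
            "mean_mass_hist_kg": mean_h,
            "mean_mass_cont_kg": mean_c,
            "retained_fraction": retained,
            "species_lost": (rich_h - rich_c).astype(int),
        }
    )
    summary = {
        "mean_aggregate_hist_kg": float(np.nanmean(agg_h)),
        "sd_aggregate_hist_kg": float(np.nanstd(agg_h, ddof=1)),
        "mean_aggregate_cont_kg": float(np.nanmean(agg_c)),
        "sd_aggregate_cont_kg": float(np.nanstd(agg_c, ddof=1)),
        "mean_mass_hist_kg": float(np.nanmean(mean_h)),
        "mean_mass_cont_kg": float(np.nanmean(mean_c)),
        "total_biomass_loss_kg": float((agg_h - agg_c).sum()),
        "mean_biomass_loss_kg": float((agg_h - agg_c).mean()),
        "percent_biomass_decline": float(
            100.0 * (1.0 - agg_c.sum() / agg_h.sum()) if agg_h.sum() > 0 else np.nan
        ),
        "mean_retained_fraction": float(np.nanmean(retained)),
    }
    return records, summary


def protection_comparison(
    records: pd.DataFrame,
    value: str = "retained_fraction",
    group: str = "protection",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-Kramer HSD pairwise comparison across protection categories.

    Uses the one-way ANOVA mean-square error and the studentized-range
    distribution with Kramer's unequal-n adjustment:
    ``q = |ȳ_i − ȳ_j| / sqrt((MSE/2)(1/n_i + 1/n_j))`` with k groups and
    N−k error degrees of freedom.
    """
    df = records[[group, value]].dropna()
    groups = {g: v[value].to_numpy(dtype=float) for g, v in df.groupby(group)}
    if len(groups) < 2:
        raise ValueError("need at least two groups for a Tukey-Kramer comparison")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs at least two observations")
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_err
    names = sorted(groups)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = a.mean() - b.mean()
            se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "mean_diff": diff,
                    "q": q,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
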