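"""Virtual-world generator with a known extirpation process.

Builds everything the defaunation pipeline consumes — smooth correlated
environmental layers, a pool of virtual species with Gaussian niches and
log-spread body masses, occurrence records, human-pressure surfaces,
protected areas, and a site×species contemporary assemblage table
produced by a logistic extirpation process biased by body mass, human
pressure and protection status.  Because the generating process is fully
known, every downstream stage can be validated by parameter recovery.

All randomness flows from a single seed through ``numpy`` Generators;
a fixed (config, seed) pair reproduces the world bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .hexgrid import VectorRegion, rasterize_region
from .raster import EnvStack, RasterGrid

__all__ = [
    "GUILDS",
    "LOCOMOTION_MODES",
    "WorldConfig",
    "VirtualSpecies",
    "TruthBundle",
    "World",
    "generate_environment",
    "generate_species_pool",
    "sample_occurrences",
    "generate_pressures",
    "place_sites",
    "apply_defaunation",
    "generate_world",
]

GUILDS = (
    "hypercarnivore",
    "insectivore",
    "myrmecophague",
    "omnivore",
    "piscivore",
    "frugivore",
    "folivore",
    "gummivore",
    "granivore",
)
LOCOMOTION_MODES = (
    "terrestrial",
    "semi-fossorial",
    "scansorial",
    "semi-aquatic",
    "arboreal",
)

# plausible value ranges the environmental layers are rescaled to,
# cycled across layers (temperature-like, seasonality-like, rainfall-like)
_LAYER_RANGES = [(12.0, 30.0), (200.0, 900.0), (300.0, 1400.0), (0.0, 100.0)]


@dataclass
class WorldConfig:
    """Full parameterisation of the virtual world.

    Defaults describe the study conditions the pipeline is validated
    under: a 100×100 km landscape at 1-km resolution, 51 species with
    body masses log-spread over 300 g – 300 kg, 73 sample sites (14 in
    strictly protected areas, 11 in sustainable-use areas), and an
    extirpation process whose logit increases with log10 body mass,
    human footprint and livestock pressure and decreases under strict
    protection.
    """

    nrows: int = 100
    ncols: int = 100
    cell_size_km: float = 1.0
    n_env_layers: int = 10
    n_species: int = 51
    n_sites: int = 73
    n_sites_strict: int = 14
    n_sites_sustainable: int = 11
    seed: int = 0
    corr_length_km: float = 30.0
    noise_sd: float = 0.02
    mass_range_g: tuple[float, float] = (300.0, 300_000.0)
    n_occurrences: int = 100
    # extirpation logit: b0 + b_mass*log10(g) + b_hfp*hfp + b_ls*ls - b_pa*strict
    beta0: float = -11.5
    beta_mass: float = 1.0
    beta_hfp: float = 0.25
    beta_ls: float = 3.5
    beta_pa: float = 4.5
    beta_pa_sustainable: float = 2.0
    corr_ls_hfp: float = 0.4
    pa_fraction: float = 0.18
    n_protected_areas: int = 6
    commission_rate: float = 0.0
    min_site_richness: int = 5
    site_richness_floor: int = 25
    multi_hot_traits: bool = False
    crs_label: str = "synthetic-km"

    def __post_init__(self) -> None:
        if self.nrows < 20 or self.ncols < 20:
            raise ValueError("grid must be at least 20x20")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.n_sites_strict + self.n_sites_sustainable > self.n_sites:
            raise ValueError("protected site counts exceed n_sites")

    def template(self) -> RasterGrid:
        return RasterGrid(
            values=np.zeros((self.nrows, self.ncols)),
            origin_x=0.0,
            origin_y=self.nrows * self.cell_size_km,
            cell_size=self.cell_size_km,
            crs_label=self.crs_label,
        )

    def region(self) -> VectorRegion:
        return VectorRegion.from_bounds(
            0.0,
            0.0,
            self.ncols * self.cell_size_km,
            self.nrows * self.cell_size_km,
            self.crs_label,
        )


@dataclass
class VirtualSpecies:
    species_id: str
    niche: dict[str, tuple[float, float]]  # layer -> (optimum, breadth)
    body_mass_g: float
    guild: str
    locomotion: str
    suitability: RasterGrid
    range_map: RasterGrid  # binary true historical range

    @property
    def log10_mass(self) -> float:
        return math.log10(self.body_mass_g)


@dataclass
class TruthBundle:
    """Ground truth of the generating process, for recovery tests."""

    historical: pd.DataFrame  # site x species incidence under the true ranges
    p_extirpation: pd.DataFrame  # true extirpation probability (NaN if absent)
    pressures: dict[str, RasterGrid]
    protected_areas: VectorRegion


@dataclass
class World:
    config: WorldConfig
    env: EnvStack
    pool: list[VirtualSpecies]
    sites: pd.DataFrame
    assemblages: pd.DataFrame
    occurrences: pd.DataFrame
    truth: TruthBundle

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.pool]

    def trait_table(self) -> pd.DataFrame:
        rows = []
        for sp in self.pool:
            row = {"species_id": sp.species_id, "body_mass_g": sp.body_mass_g}
            for g in GUILDS:
                row[g] = int(g == sp.guild)
            for m in LOCOMOTION_MODES:
                row[m] = int(m == sp.locomotion)
            rows.append(row)
        return pd.DataFrame(rows).set_index("species_id")


# -- environment --------------------------------------------------------


def _smooth_field(rng: np.random.Generator, config: WorldConfig) -> np.ndarray:
    """Standardised smooth random field: low-frequency sinusoids + noise."""
    ny, nx = config.nrows, config.ncols
    yy, xx = np.mgrid[0:ny, 0:nx] * config.cell_size_km
    if not np.isfinite(config.corr_length_km):
        return np.zeros((ny, nx))
    f = np.zeros((ny, nx))
    for _ in range(6):
        wavelength = config.corr_length_km * rng.uniform(1.0, 4.0)
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / wavelength
        f += rng.uniform(0.4, 1.0) * np.sin(
            k * (np.cos(theta) * xx + np.sin(theta) * yy) + phase
        )
    f += rng.normal(0.0, config.noise_sd, size=f.shape)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_environment(config: WorldConfig) -> EnvStack:
    """Environmental stack: ``BIO1..BIOn`` plus ``elevation``.

    Layers are smooth correlated fields rescaled to plausible bioclim
    ranges.  The last BIO layer is generated as a near-copy of the first
    (|r| > 0.8) so that collinearity pre-screening has work to do; the
    remaining layers are mutually weakly correlated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    template = config.template()
    fields = [_smooth_field(rng, config) for _ in range(config.n_env_layers)]
    if config.n_env_layers >= 2 and np.isfinite(config.corr_length_km):
        # engineered collinear pair: last layer duplicates the first
        fields[-1] = 0.97 * fields[0] + 0.03 * _smooth_field(rng, config)
    layers: dict[str, RasterGrid] = {}
    for i, f in enumerate(fields):
        lo, hi = _LAYER_RANGES[i % len(_LAYER_RANGES)]
        z = (f - f.min()) / (f.max() - f.min()) if np.ptp(f) > 0 else f * 0 + 0.5
        layers[f"BIO{i + 1}"] = template.like(lo + z * (hi - lo))
    elev = _smooth_field(rng, config)
    z = (elev - elev.min()) / (elev.max() - elev.min()) if np.ptp(elev) > 0 else elev + 0.5
    layers["elevation"] = template.like(z * 1200.0)
    return EnvStack(layers)


# -- species pool -------------------------------------------------------


def _species_suitability(
    env: EnvStack, niche: dict[str, tuple[float, float]]
) -> np.ndarray:
    log_s = np.zeros(env.template.shape)
    for name, (mu, sigma) in niche.items():
        x = env[name].values
        log_s -= (x - mu) ** 2 / (2.0 * sigma**2)
    return np.exp(log_s)


def generate_species_pool(
    config: WorldConfig, env: EnvStack, max_retries: int = 50
) -> list[VirtualSpecies]:
    """Pool of virtual species with Gaussian niches on 2–3 random layers.

    Suitability is the product of per-layer Gaussian responses; the true
    historical range is the region where suitability reaches half its
    landscape maximum.  Species drawing an empty range are re-drawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    template = env.template
    names = env.names
    lo_m, hi_m = config.mass_range_g
    pool: list[VirtualSpecies] = []
    width = len(str(config.n_species))
    for i in range(config.n_species):
        mass = 10 ** rng.uniform(math.log10(lo_m), math.log10(hi_m))
        guild = GUILDS[rng.integers(len(GUILDS))]
        loco = LOCOMOTION_MODES[rng.integers(len(LOCOMOTION_MODES))]
        for attempt in range(max_retries):
            # community structure: every species responds to the same two
            # primary gradients (optima near the regional core, narrow
            # breadth) plus one broad secondary layer, so ranges overlap
            # in a species-rich core the way a biome hosts a fauna
            primary = names[:2]
            extra = [str(rng.choice(names[2:]))] if len(names) > 2 and rng.random() < 0.7 else []
            niche = {}
            for name in primary:
                vals = env[name].valid_values()
                mu = float(np.quantile(vals, rng.uniform(0.35, 0.65)))
                sigma = float(max(vals.std(), 1e-9) * rng.uniform(0.45, 0.8))
                niche[name] = (mu, sigma)
            for name in extra:
                vals = env[name].valid_values()
                mu = float(np.quantile(vals, rng.uniform(0.2, 0.8)))
                sigma = float(max(vals.std(), 1e-9) * rng.uniform(1.2, 2.0))
                niche[name] = (mu, sigma)
            suit = _species_suitability(env, niche)
            rng_map = (suit >= 0.5 * suit.max()).astype(float)
            if rng_map.sum() >= 10:  # viable range
                break
        else:
            raise RuntimeError(f"could not draw a non-empty range for species {i}")
        pool.append(
            VirtualSpecies(
                species_id=f"sp{i + 1:0{width}d}",
                niche=niche,
                body_mass_g=mass,
                guild=guild,
                locomotion=loco,
                suitability=template.like(suit),
                range_map=template.like(rng_map),
            )
        )
    return pool


def sample_occurrences(
    species: VirtualSpecies, n_points: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Occurrence records within the true range, weighted by suitability.

    Cells are drawn without replacement until the range is exhausted,
    then the pool resets, so heavy sampling covers the range uniformly
    in proportion to suitability.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mask = species.range_map.values > 0
    if not mask.any():
        raise ValueError(f"species {species.species_id} has an empty range")
    gx, gy = species.range_map.cell_centers()
    cx, cy = gx[mask], gy[mask]
    w = species.suitability.values[mask]
    p = w / w.sum()
    n_cells = cx.size
    if n_points > n_cells:
        warnings.warn(
            f"{species.species_id}: requested {n_points} occurrences from a "
            f"range of {n_cells} cells; sampling the range repeatedly"
        )
    picks: list[np.ndarray] = []
    remaining = n_points
    while remaining > 0:
        take = min(remaining, n_cells)
        picks.append(rng.choice(n_cells, size=take, replace=False, p=p, shuffle=False))
        remaining -= take
    idx = np.concatenate(picks) if picks else np.empty(0, dtype=int)
    return pd.DataFrame(
        {"species": species.species_id, "x": cx[idx], "y": cy[idx]}
    )


# -- pressures and protection ------------------------------------------


def generate_pressures(
    config: WorldConfig, env: EnvStack
) -> tuple[dict[str, RasterGrid], VectorRegion]:
    """Driver surfaces {ls, crop, past, hfp, agb, pas} + PA polygons.

    ``ls`` (livestock pressure), ``crop`` and ``past`` are correlated
    proportions in [0, 1]; ``hfp`` is a human-footprint-like index with
    corr(ls, hfp) ≈ ``config.corr_ls_hfp``; ``agb`` (above-ground
    biomass, Mg/ha) tracks a rainfall-like environmental layer; ``pas``
    is the binary rasterisation of randomly placed protected-area
    polygons tagged strict or sustainable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    template = config.template()
    z_ls = _smooth_field(rng, config)
    z_ind = _smooth_field(rng, config)
    z_crop = _smooth_field(rng, config)
    z_past = _smooth_field(rng, config)
    rho = config.corr_ls_hfp
    z_hfp = rho * z_ls + math.sqrt(max(0.0, 1 - rho**2)) * z_ind

    def unit(z, lo=0.0, hi=1.0):
        return np.clip(0.5 + 0.25 * z, lo, hi)

    pressures = {
        "ls": template.like(unit(z_ls)),
        "crop": template.like(unit(0.6 * z_ls + 0.8 * z_crop)),
        "past": template.like(unit(0.7 * z_ls + 0.7 * z_past)),
        "hfp": template.like(np.clip(25.0 + 8.0 * z_hfp, 0.0, None)),
    }
    # biomass positively tied to the most rainfall-like layer (index 2 ring)
    agb_layer = env.names[min(2, len(env.names) - 1)]
    x = env[agb_layer].values
    z_env = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    rough = replace(config, corr_length_km=config.corr_length_km / 3.0)
    pressures["agb"] = template.like(
        np.clip(60.0 + 8.0 * z_env + 24.0 * _smooth_field(rng, rough), 0.0, None)
    )

    # protected areas: discs covering ~pa_fraction of the landscape,
    # sited preferentially on low-pressure land (the usual "residual
    # reserve" pattern: parks go where human pressure is lowest)
    width = config.ncols * config.cell_size_km
    height = config.nrows * config.cell_size_km
    polys = []
    if config.pa_fraction > 0 and config.n_protected_areas > 0:
        target = config.pa_fraction * width * height
        r = math.sqrt(target / (config.n_protected_areas * math.pi))
        pressure_index = (
            (pressures["hfp"].values - pressures["hfp"].values.mean())
            / max(pressures["hfp"].values.std(), 1e-9)
            + (pressures["ls"].values - pressures["ls"].values.mean())
            / max(pressures["ls"].values.std(), 1e-9)
        )
        cutoff = np.quantile(pressure_index, 0.35)
        for k in range(config.n_protected_areas):
            for _ in range(200):
                cx = rng.uniform(r, width - r)
                cy = rng.uniform(r, height - r)
                row, col = template.index_of(cx, cy)
                if pressure_index[row, col] <= cutoff:
                    break
            category = "strict" if k % 2 == 0 else "sustainable"
            polys.append(
                (f"pa{k + 1}", Point(cx, cy).buffer(r, quad_segs=24), {"category": category})
            )
    pas_region = VectorRegion(polys, config.crs_label)
    if polys:
        pressures["pas"] = rasterize_region(pas_region, template)
    else:
        pressures["pas"] = template.like(np.zeros(template.shape))
    return pressures, pas_region


# -- sites and defaunation ----------------------------------------------


def _sample_cells(rng, mask: np.ndarray, n: int, template: RasterGrid):
    rows, cols = np.nonzero(mask)
    if rows.size < n:
        raise ValueError(f"cannot place {n} sites on {rows.size} eligible cells")
    pick = rng.choice(rows.size, size=n, replace=False, shuffle=False)
    x = template.origin_x + (cols[pick] + 0.5) * template.cell_size
    y = template.origin_y - (rows[pick] + 0.5) * template.cell_size
    return rows[pick], cols[pick], x, y


def place_sites(
    config: WorldConfig,
    pressures: dict[str, RasterGrid],
    pas_region: VectorRegion,
    pool: list[VirtualSpecies] | None = None,
) -> pd.DataFrame:
    """Sample-site locations stratified by protection category.

    Exactly ``n_sites_strict`` sites fall in strictly protected areas and
    ``n_sites_sustainable`` in sustainable-use areas, mirroring the
    observed mix of assemblage protection statuses; the remainder are
    scattered over unprotected land.  When the species pool is supplied,
    sites are restricted to cells whose true historical richness reaches
    ``site_richness_floor`` — compiled assemblage data likewise come
    from places that support a mammal community — relaxed per category
    if a protection class offers too few such cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    template = config.template()
    if pool is not None:
        hist_richness = np.sum([sp.range_map.values for sp in pool], axis=0)
    else:
        hist_richness = None
    strict = pas_region.with_attr("category", "strict")
    sust = pas_region.with_attr("category", "sustainable")
    strict_mask = (
        rasterize_region(strict, template).values > 0
        if strict.polygons
        else np.zeros(template.shape, bool)
    )
    sust_mask = (
        rasterize_region(sust, template).values > 0
        if sust.polygons
        else np.zeros(template.shape, bool)
    )
    sust_mask &= ~strict_mask
    none_mask = ~(strict_mask | sust_mask)
    records = []
    for category, mask, n in [
        ("strict", strict_mask, config.n_sites_strict),
        ("sustainable", sust_mask, config.n_sites_sustainable),
        (
            "none",
            none_mask,
            config.n_sites - config.n_sites_strict - config.n_sites_sustainable,
        ),
    ]:
        if n == 0:
            continue
        if hist_richness is not None:
            floor = config.site_richness_floor
            eligible = mask & (hist_richness >= floor)
            while eligible.sum() < n and floor > 0:
                floor //= 2
                eligible = mask & (hist_richness >= floor)
            if floor < config.site_richness_floor:
                warnings.warn(
                    f"richness floor relaxed to {floor} for {category!r} sites"
                )
            mask = eligible
        rr, cc, x, y = _sample_cells(rng, mask, n, template)
        for r, c, xi, yi in zip(rr, cc, x, y):
            records.append((xi, yi, int(r), int(c), category))
    rng.shuffle(records)
    df = pd.DataFrame(records, columns=["x", "y", "row", "col", "protection"])
    df.insert(0, "site_id", [f"site{i + 1:03d}" for i in range(len(df))])
    return df


def apply_defaunation(
    pool: list[VirtualSpecies],
    sites: pd.DataFrame,
    pressures: dict[str, RasterGrid],
    config: WorldConfig,
    pas_region: VectorRegion,
    seed: int | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Realise the contemporary assemblages from the extirpation model.

    For each species historically present at a site, the extirpation
    probability is ``logistic(b0 + b_mass*log10(mass) + b_hfp*hfp +
    b_ls*ls - b_pa*[strict PA] - b_pa_sust*[sustainable PA])``;
    survivors form the contemporary incidence.  Sites falling below the minimum-richness inclusion rule
    are dropped, as in compiled field assemblage data.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 505])
    )
    ids = [sp.species_id for sp in pool]
    rows = sites["row"].to_numpy()
    cols = sites["col"].to_numpy()
    hist = np.stack(
        [sp.range_map.values[rows, cols] > 0 for sp in pool], axis=1
    )  # sites x species
    hfp = pressures["hfp"].values[rows, cols]
    ls = pressures["ls"].values[rows, cols]
    strict = (sites["protection"] == "strict").to_numpy()
    sust = (sites["protection"] == "sustainable").to_numpy()
    logit = (
        config.beta0
        + config.beta_mass * np.array([sp.log10_mass for sp in pool])[None, :]
        + config.beta_hfp * hfp[:, None]
        + config.beta_ls * ls[:, None]
        - config.beta_pa * strict[:, None]
        - config.beta_pa_sustainable * sust[:, None]
    )
    with np.errstate(over="ignore"):
        p_ext = 1.0 / (1.0 + np.exp(-logit))
    draws = rng.random(p_ext.shape)
    extirpated = hist & (draws < p_ext)
    contemporary = hist & ~extirpated
    if config.commission_rate > 0:
        commission = (~hist) & (rng.random(hist.shape) < config.commission_rate)
        contemporary = contemporary | commission
    richness = contemporary.sum(axis=1)
    keep = richness >= config.min_site_richness
    if not keep.any():
        raise ValueError(
            "no site passes the minimum-richness filter; "
            "weaken the extirpation coefficients"
        )
    site_cols = ["site_id", "x", "y", "protection"]
    assemblages = pd.concat(
        [
            sites.loc[keep, site_cols].reset_index(drop=True),
            pd.DataFrame(contemporary[keep].astype(int), columns=ids),
        ],
        axis=1,
    )
    hist_df = pd.concat(
        [
            sites.loc[keep, site_cols].reset_index(drop=True),
            pd.DataFrame(hist[keep].astype(int), columns=ids),
        ],
        axis=1,
    )
    p_df = pd.DataFrame(
        np.where(hist[keep], p_ext[keep], np.nan),
        columns=ids,
        index=hist_df["site_id"],
    )
    truth = TruthBundle(
        historical=hist_df,
        p_extirpation=p_df,
        pressures=pressures,
        protected_areas=pas_region,
    )
    return assemblages, truth


def generate_world(config: WorldConfig | None = None) -> World:
    """End-to-end world generation under one config (fully seeded)."""
    config = config or WorldConfig()
    env = generate_environment(config)
    pool = generate_species_pool(config, env)
    pressures, pas_region = generate_pressures(config, env)
    sites = place_sites(config, pressures, pas_region, pool)
    assemblages, truth = apply_defaunation(pool, sites, pressures, config, pas_region)
    occ_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
    occurrences = pd.concat(
        [sample_occurrences(sp, config.n_occurrences, occ_rng) for sp in pool],
        ignore_index=True,
    )
    # keep only sites retained by the richness filter
    sites = sites[sites["site_id"].isin(assemblages["site_id"])].reset_index(drop=True)
    return World(
        config=config,
        env=env,
        pool=pool,
        sites=sites,
        assemblages=assemblages,
        occurrences=occurrences,
        truth=truth,
    )
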