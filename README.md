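# defauna

Reconstructing mammal defaunation across a gridded landscape.

Regional defaunation — the loss of medium- to large-bodied mammal
populations since historical times — cannot be observed directly: there
is no census of what lived where centuries ago. This package implements
the standard indirect reconstruction used in macroecology, as a tested,
reusable pipeline for ecologists and conservation modellers:

1. **Historical distributions.** For each species, a presence-background
   maximum-entropy model (MaxEnt-style) fitted to occurrence records and
   climatic/topographic layers. Suitability is the Gibbs distribution
   `p(cell) ∝ exp(λ·f(cell))` whose weights λ maximise the L1-penalised
   log-likelihood; candidate layers are pre-screened at |r| < 0.8, model
   accuracy is scored by replicated test-split AUC, and each suitability
   surface is binarised at the training threshold that predicts the
   smallest area. Stacking the binary maps gives historical richness.
2. **Contemporary distributions.** Site × species incidence tables from
   field assemblages, interpolated to a raster by inverse-distance
   weighting (`w_i = d_i^-p`, p = 2 by default).
3. **Defaunation.** `D = historical − contemporary` richness per cell,
   summarised over a grid of regular 5-km-edge hexagons (64.95 km²
   each), with percent-loss bands, per-species range loss, and
   assemblage *downsizing* (loss of aggregate/mean body mass), compared
   across protection categories with a Tukey-Kramer HSD.
4. **Drivers.** Stochastic gradient-boosted regression trees (squared
   error, random-search hyperparameters under 10-fold CV) regress
   hexcell defaunation on landscape covariates — livestock pressure,
   cropland, pasture, human footprint, above-ground biomass, protected
   area — attributed with exact interventional Shapley values.
5. **Functional diversity.** Gower distances on mixed traits (log10
   body mass + binary guild/locomotion), PCoA with Cailliez correction,
   m axes chosen by embedding quality R² > 0.75, convex-hull functional
   richness standardised by the species pool, and a Gaussian GLM of FD
   loss on drivers.

Because real inputs (climate grids, occurrence archives, census and
footprint layers) are large and external, the package ships a fully
specified **virtual world**: correlated environmental fields, 51
virtual species with Gaussian niches and log-spread body masses
(300 g – 300 kg), 73 candidate assemblage sites, human-pressure
surfaces, protected areas, and a logistic extirpation process biased by
body mass, human pressure and protection. Every stage of the analysis
can therefore be validated by parameter recovery against a known truth.

## Worked example

```python
import numpy as np

from defauna import (
    WorldConfig, generate_world, run_sdm, contemporary_richness_surface,
    defaunation_raster, loss_band_summary, historical_composition,
    augment_historical, downsizing, protection_comparison, hexagon_area,
)

cfg = WorldConfig(nrows=40, ncols=40, n_env_layers=6, n_species=12,
                  n_sites=30, n_sites_strict=6, n_sites_sustainable=4,
                  n_occurrences=60, site_richness_floor=6, seed=11)
world = generate_world(cfg)
print(f"assemblages retained: {len(world.assemblages)}")

sdms, hist_richness, retained = run_sdm(world.occurrences, world.env, seed=1)
aucs = [r.eval_report.mean_auc for r in sdms.values()]
print(f"predictors retained after |r|<0.8 screening: {len(retained)}")
print(f"mean test AUC over {len(aucs)} species: {np.mean(aucs):.3f}")

cont = contemporary_richness_surface(world.assemblages, world.env.template)
d = defaunation_raster(hist_richness, cont)

hist = augment_historical(
    historical_composition({s: r.binary for s, r in sdms.items()},
                           world.assemblages),
    world.assemblages)
records, summary = downsizing(world.assemblages, hist,
                              world.trait_table()["body_mass_g"] / 1000)
print(f"mean body mass: {summary['mean_mass_hist_kg']:.1f} kg historical -> "
      f"{summary['mean_mass_cont_kg']:.1f} kg contemporary")
tukey = protection_comparison(records)
row = tukey.query("group_a=='none' and group_b=='strict'").iloc[0]
print(f"strict PAs retain {row.mean_b:.0%} of historical biomass vs "
      f"{row.mean_a:.0%} outside (Tukey-Kramer p = {row.p:.4f})")
print(f"one 5-km hexcell covers {hexagon_area(5.0):.2f} km^2")
```

Output:

```
assemblages retained: 18
predictors retained after |r|<0.8 screening: 5
mean test AUC over 12 species: 0.899
mean body mass: 52.4 kg historical -> 49.6 kg contemporary
strict PAs retain 100% of historical biomass vs 63% outside (Tukey-Kramer p = 0.0146)
one 5-km hexcell covers 64.95 km^2
```

Reading it: the richness-screened assemblage compilation keeps 18 of the
30 candidate sites; the species models discriminate suitable from
background conditions (AUC ≈ 0.9); communities have downsized (mean
body mass fell); and strictly protected sites retain a significantly
larger fraction of their historical mammal biomass than unprotected
ones.

## Command line

Each stage is also a subcommand of the `defauna` CLI operating on a run
directory, with a YAML config and a global `--seed`:

```sh
defauna simulate  --outdir run --seed 1     # write the virtual world
defauna pipeline  --outdir run --seed 1     # simulate ... drivers, end to end
```

The pipeline writes a `manifest.json` with per-stage seeds, wall times
and SHA-256 checksums of every artefact; rerunning the same config
reproduces the checksums.

## Layout

| module | role |
| --- | --- |
| `defauna.raster`, `defauna.hexgrid` | raster/vector data model, ASCII-grid + GeoJSON I/O, hexagonal grids, zonal statistics, terrain slope |
| `defauna.synth` | the virtual world generator and its extirpation truth |
| `defauna.maxent` | presence-background MaxEnt SDMs (`MaxentSDM` → `MaxentResults`), thresholds, stacking |
| `defauna.idw` | assemblage tables and inverse-distance-weighted surfaces |
| `defauna.metrics` | defaunation, loss bands, range loss, downsizing, Tukey-Kramer |
| `defauna.fd` | Gower / PCoA / convex-hull functional richness, FD-loss GLM |
| `defauna.gbm` | boosted regression trees (`GradientBoostedTrees` → `GBTResults`), random-search CV, interventional SHAP |
| `defauna.pipeline`, `defauna.cli` | orchestration, manifest, command line |
| `defauna.recovery` | the end-to-end parameter-recovery study |

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
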