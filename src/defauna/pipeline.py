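"""End-to-end orchestration of the defaunation analysis.

Stage order (a DAG, executed in dependency order):

    simulate → sdm → interpolate → defaunate → downsize → fd → drivers

Each stage reads the declared inputs from the run directory, writes its
outputs there, and records parameters, seeds, wall time and output
checksums in a manifest, so a rerun under the same config is
reproducible artefact for artefact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fd as fdmod
from . import gbm, idw, maxent, metrics
from .hexgrid import build_hexgrid, read_region
from .raster import read_raster, write_raster
from .synth import WorldConfig, generate_world
from .worldio import read_env_stack, read_occurrences, read_traits, write_world

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "sdm", "interpolate", "defaunate", "downsize", "fd", "drivers")
STAGE_DEPS = {
    "simulate": (),
    "sdm": ("simulate",),
    "interpolate": ("simulate",),
    "defaunate": ("sdm", "interpolate"),
    "downsize": ("sdm", "simulate"),
    "fd": ("sdm", "simulate"),
    "drivers": ("defaunate",),
}
# seed offsets keep stage streams independent under one global seed
STAGE_SEED_OFFSET = {name: 10 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    outdir: str = "defauna_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    world: dict = field(default_factory=dict)  # WorldConfig overrides
    # sdm
    r_max: float = 0.8
    n_replicates: int = 10
    test_fraction: float = 0.10
    beta_scale: float = 0.15
    max_iter: int = 100
    # interpolation
    idw_power: float = 2.0
    species_cutoff: float = 0.5
    # hexgrid / drivers
    hex_edge_km: float = 5.0
    min_hexcell_richness: float | None = 5.0
    train_fraction: float = 0.75
    n_candidates: int = 25
    cv_folds: int = 10
    search_space: dict = field(default_factory=dict)
    # fd
    fd_quality_threshold: float = 0.75
    fd_m_cap: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(outdir: Path, relpath: str, needed_by: str, producer: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {relpath!r}; run stage {producer!r} first"
        )
    return p


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return config.seed + STAGE_SEED_OFFSET[stage]


# -- stage implementations ---------------------------------------------


def _run_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    wc = WorldConfig(seed=_stage_seed(config, "simulate"), **config.world)
    world = generate_world(wc)
    paths = write_world(world, outdir)
    (outdir / "world_config.json").write_text(
        json.dumps(dataclasses.asdict(wc), default=str)
    )
    return [*paths.values(), str(outdir / "world_config.json")]


def _run_sdm(config: PipelineConfig, outdir: Path) -> list[str]:
    env = read_env_stack(_require(outdir, "env", "sdm", "simulate"))
    occ = read_occurrences(_require(outdir, "occurrences.csv", "sdm", "simulate"))
    results, richness, retained = maxent.run_sdm(
        occ,
        env,
        r_max=config.r_max,
        n_rep=config.n_replicates,
        test_frac=config.test_fraction,
        beta_scale=config.beta_scale,
        max_iter=config.max_iter,
        seed=_stage_seed(config, "sdm"),
    )
    sdm_dir = outdir / "sdm"
    sdm_dir.mkdir(exist_ok=True)
    written = []
    reports = {}
    for sp, res in results.items():
        written.append(str(write_raster(res.suitability, sdm_dir / f"{sp}_suitability.asc")))
        written.append(str(write_raster(res.binary, sdm_dir / f"{sp}_binary.asc")))
        reports[sp] = {
            "auc_per_replicate": res.eval_report.auc_per_replicate,
            "mean_auc": res.eval_report.mean_auc,
            "threshold": res.threshold_report.to_dict(),
        }
    written.append(str(write_raster(richness, outdir / "historical_richness.asc")))
    rep_path = sdm_dir / "reports.json"
    rep_path.write_text(json.dumps({"retained_layers": retained, "species": reports}))
    written.append(str(rep_path))
    return written


def _run_interpolate(config: PipelineConfig, outdir: Path) -> list[str]:
    asm = idw.load_assemblages(
        _require(outdir, "assemblages.csv", "interpolate", "simulate")
    )
    template = read_raster(
        _require(outdir, "env", "interpolate", "simulate") / "elevation.asc"
    )
    cfg = idw.IDWConfig(power=config.idw_power)
    written = []
    rich = idw.contemporary_richness_surface(asm, template, cfg)
    written.append(str(write_raster(rich, outdir / "contemporary_richness.asc")))
    sp_dir = outdir / "contemporary"
    sp_dir.mkdir(exist_ok=True)
    for sp in idw.species_columns(asm):
        surf = idw.contemporary_species_surface(
            asm, sp, template, cfg, cutoff=config.species_cutoff
        )
        written.append(str(write_raster(surf, sp_dir / f"{sp}_binary.asc")))
    return written


def _run_defaunate(config: PipelineConfig, outdir: Path) -> list[str]:
    hist = read_raster(_require(outdir, "historical_richness.asc", "defaunate", "sdm"))
    cont = read_raster(
        _require(outdir, "contemporary_richness.asc", "defaunate", "interpolate")
    )
    d = metrics.defaunation_raster(hist, cont)
    written = [
        str(write_raster(d.difference, outdir / "defaunation.asc")),
        str(write_raster(d.percent_loss, outdir / "defaunation_percent.asc")),
    ]
    bands = metrics.loss_band_summary(d.percent_loss)
    bands_path = outdir / "loss_bands.json"
    bands_path.write_text(json.dumps(bands))
    written.append(str(bands_path))
    region = read_region(_require(outdir, "region.geojson", "defaunate", "simulate"))
    grid = build_hexgrid(region, config.hex_edge_km)
    press_dir = _require(outdir, "pressures", "defaunate", "simulate")
    covs = {p.stem: read_raster(p) for p in sorted(press_dir.glob("*.asc"))}
    cells = metrics.defaunation_by_hexcell(
        d.difference, grid, covs, covariate_stats={"pas": "mean"},
        historical=hist, min_historical_richness=config.min_hexcell_richness,
    )
    cells_path = outdir / "hexcells.csv"
    cells.to_csv(cells_path, index=False)
    written.append(str(cells_path))
    return written


def _load_compositions(outdir: Path, stage: str):
    asm = idw.load_assemblages(_require(outdir, "assemblages.csv", stage, "simulate"))
    sdm_dir = _require(outdir, "sdm", stage, "sdm")
    binary_maps = {
        p.stem.removesuffix("_binary"): read_raster(p)
        for p in sorted(sdm_dir.glob("*_binary.asc"))
    }
    hist = metrics.augment_historical(
        metrics.historical_composition(binary_maps, asm), asm
    )
    return asm, hist, binary_maps


def _run_downsize(config: PipelineConfig, outdir: Path) -> list[str]:
    asm, hist, binary_maps = _load_compositions(outdir, "downsize")
    traits = read_traits(_require(outdir, "traits.csv", "downsize", "simulate"))
    mass_kg = traits["body_mass_g"] / 1000.0
    records, summary = metrics.downsizing(asm, hist, mass_kg)
    written = []
    rec_path = outdir / "downsizing.csv"
    records.to_csv(rec_path, index=False)
    written.append(str(rec_path))
    sum_path = outdir / "downsizing_summary.json"
    sum_path.write_text(json.dumps(summary))
    written.append(str(sum_path))
    tukey = metrics.protection_comparison(records)
    tuk_path = outdir / "tukey_protection.csv"
    tukey.to_csv(tuk_path, index=False)
    written.append(str(tuk_path))
    loss = metrics.species_range_loss(binary_maps, asm)
    loss_path = outdir / "range_loss.csv"
    loss.to_csv(loss_path, index=False)
    written.append(str(loss_path))
    return written


def _run_fd(config: PipelineConfig, outdir: Path) -> list[str]:
    asm, hist, _ = _load_compositions(outdir, "fd")
    traits = read_traits(_require(outdir, "traits.csv", "fd", "simulate"))
    table, res, m = fdmod.fd_site_table(
        hist, asm, traits, config.fd_quality_threshold, config.fd_m_cap
    )
    written = []
    fd_path = outdir / "fd.csv"
    table.to_csv(fd_path, index=False)
    written.append(str(fd_path))
    # site-level covariates for the Gaussian GLM on FD loss
    rows_cols = {}
    press_dir = _require(outdir, "pressures", "fd", "simulate")
    covs = {p.stem: read_raster(p) for p in sorted(press_dir.glob("*.asc"))}
    r, c = covs["hfp"].index_of(asm["x"].to_numpy(), asm["y"].to_numpy())
    X = pd.DataFrame(
        {
            "agb": covs["agb"].values[r, c],
            "protected_area": covs["pas"].values[r, c],
            "human_footprint": covs["hfp"].values[r, c],
            "defaunation": (
                hist[idw.species_columns(asm)].to_numpy().sum(axis=1)
                - asm[idw.species_columns(asm)].to_numpy().sum(axis=1)
            ),
        }
    )
    coef, _fit = fdmod.glm_fd(table["fd_loss"], X)
    glm_path = outdir / "fd_glm.csv"
    coef.to_csv(glm_path, index=False)
    written.append(str(glm_path))
    meta = outdir / "fd_meta.json"
    meta.write_text(
        json.dumps(
            {"m": m, "correction": res.correction,
             "r_squared": {str(k): res.r_squared(k) for k in range(1, m + 1)}}
        )
    )
    written.append(str(meta))
    return written


def _run_drivers(config: PipelineConfig, outdir: Path) -> list[str]:
    cells = pd.read_csv(_require(outdir, "hexcells.csv", "drivers", "defaunate"))
    seed = _stage_seed(config, "drivers")
    data = cells.drop(columns=["cell_id"])
    train, test = gbm.split_data(data, config.train_fraction, seed)
    features = [c for c in data.columns if c != "defaunation"]
    cv = gbm.tune_random_search(
        train,
        "defaunation",
        space=config.search_space or None,
        n_candidates=config.n_candidates,
        k=config.cv_folds,
        seed=seed,
        test=(test[features].to_numpy(), test["defaunation"].to_numpy()),
    )
    written = []
    model_path = outdir / "gbm_model.json"
    cv.results.to_json(model_path)
    written.append(str(model_path))
    cv_path = outdir / "gbm_cv.json"
    cv_path.write_text(json.dumps(cv.to_dict()))
    written.append(str(cv_path))
    explanation = cv.results.shap(test[features], seed=seed)
    shap_path = outdir / "shap_values.csv"
    explanation.to_frame().to_csv(shap_path, index=False)
    written.append(str(shap_path))
    imp = pd.DataFrame(
        {
            "feature": explanation.importance().index,
            "mean_abs_phi": explanation.importance().to_numpy(),
            "sign_trend": explanation.sign_trend()[
                explanation.importance().index
            ].to_numpy(),
        }
    )
    imp_path = outdir / "shap_importance.csv"
    imp.to_csv(imp_path, index=False)
    written.append(str(imp_path))
    return written


_STAGE_FN = {
    "simulate": _run_simulate,
    "sdm": _run_sdm,
    "interpolate": _run_interpolate,
    "defaunate": _run_defaunate,
    "downsize": _run_downsize,
    "fd": _run_fd,
    "drivers": _run_drivers,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    for stage in enabled:
        for dep in STAGE_DEPS[stage]:
            if dep not in enabled:
                # upstream artefacts may exist from a previous run
                pass
        log.info("running stage %s (seed %d)", stage, _stage_seed(config, stage))
        t0 = time.perf_counter()
        outputs = _STAGE_FN[stage](config, outdir)
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {
            "seed": _stage_seed(config, stage),
            "wall_time_s": round(elapsed, 3),
            "outputs": {
                str(Path(p).relative_to(outdir)): _sha256(Path(p)) for p in outputs
            },
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
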