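"""Reading and writing the pipeline's file formats.

Everything is plain text: ESRI ASCII rasters, CSV tables, GeoJSON
vectors — the same formats the pipeline accepts for real data, so the
synthetic world doubles as format documentation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hexgrid import read_region, write_region
from .raster import EnvStack, read_raster, write_raster
from .synth import World

__all__ = [
    "write_world",
    "read_env_stack",
    "read_occurrences",
    "read_traits",
]


def write_world(world: World, outdir: str | Path) -> dict[str, str]:
    """Write every world artefact; returns a name → path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    env_dir = outdir / "env"
    env_dir.mkdir(exist_ok=True)
    for name, layer in world.env.layers.items():
        paths[f"env/{name}"] = str(write_raster(layer, env_dir / f"{name}.asc"))
    press_dir = outdir / "pressures"
    press_dir.mkdir(exist_ok=True)
    for name, layer in world.truth.pressures.items():
        paths[f"pressures/{name}"] = str(
            write_raster(layer, press_dir / f"{name}.asc")
        )
    occ = outdir / "occurrences.csv"
    world.occurrences.to_csv(occ, index=False)
    paths["occurrences"] = str(occ)
    asm = outdir / "assemblages.csv"
    world.assemblages.to_csv(asm, index=False)
    paths["assemblages"] = str(asm)
    hist = outdir / "historical_truth.csv"
    world.truth.historical.to_csv(hist, index=False)
    paths["historical_truth"] = str(hist)
    traits = outdir / "traits.csv"
    world.trait_table().reset_index().to_csv(traits, index=False)
    paths["traits"] = str(traits)
    pas = outdir / "protected_areas.geojson"
    write_region(world.truth.protected_areas, pas)
    paths["protected_areas"] = str(pas)
    region = outdir / "region.geojson"
    write_region(world.config.region(), region)
    paths["region"] = str(region)
    return paths


def read_env_stack(env_dir: str | Path) -> EnvStack:
    """Load every ``.asc`` raster in a directory as an environment stack."""
    env_dir = Path(env_dir)
    layers = {}
    for path in sorted(env_dir.glob("*.asc")):
        layers[path.stem] = read_raster(path)
    if not layers:
        raise FileNotFoundError(f"no .asc rasters in {env_dir}")
    # BIO1..BIOn then elevation, matching generation order
    def key(name: str):
        if name.startswith("BIO") and name[3:].isdigit():
            return (0, int(name[3:]))
        return (1, name)

    return EnvStack({n: layers[n] for n in sorted(layers, key=key)})


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns {sorted(missing)}")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species_id" not in df.columns or "body_mass_g" not in df.columns:
        raise ValueError("trait table needs species_id and body_mass_g columns")
    return df.set_index("species_id")


read_protected_areas = read_region
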