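"""Orchestration: simulate -> morphometry -> occupancy model -> report.

A single root seed governs every stage; per-stage seeds are derived with the
documented counter scheme (stage i uses ``child_seed(root, 100 + i)``) and
recorded in the run manifest.  All output tables are TSV with ``#``-prefixed
metadata headers whose content is deterministic, so identical config + seed
produce byte-identical table files; wall-clock and versions live only in the
manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .morphometry import (
    InputError,
    measure_population,
    read_points_csv,
    sphere_equivalent_radius,
    summarize_strains,
)
from .occupancy import (
    DEFAULT_RELAXED_RATIO,
    CargoMix,
    CargoSpecies,
    ModelParams,
    compare_strains,
    default_cargo_mixes,
    default_probe_cargoes,
    k_grid,
)
from .oracle import mc_partition, recover_parameters
from .synthetic import StrainConfig, VesicleSurface, child_seed, generate_strain

log = logging.getLogger("vesiclekit")


@dataclass(frozen=True)
class RunConfig:
    """Full-pipeline settings; ``presets`` names built-in strains."""

    seed: int = 0
    out_dir: str = "vesiclekit-run"
    presets: tuple[str, ...] = synthetic.PRESET_NAMES
    strains: tuple[StrainConfig, ...] = ()  # explicit configs, in addition to presets
    n_vesicles: int = 500
    reference_strain: str = "WT"
    n_boot: int = 2000
    model_params: ModelParams = field(default_factory=ModelParams)
    probe_cargoes: tuple[CargoSpecies, ...] = field(
        default_factory=lambda: tuple(default_probe_cargoes())
    )
    grid_R_av_nm: tuple[float, float, float] = (2.0, 20.0, 0.5)  # min, max, step
    grid_r_cargo_nm: tuple[float, float, float] = (0.5, 10.0, 0.25)
    relaxed_ratio_threshold: float = DEFAULT_RELAXED_RATIO
    oracle_n: int = 20_000  # per-run oracle spot check


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run config (keys mirror RunConfig fields)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise InputError(f"run config {path} is not a mapping")
    kwargs: dict = {}
    simple = (
        "seed",
        "out_dir",
        "n_vesicles",
        "reference_strain",
        "n_boot",
        "relaxed_ratio_threshold",
        "oracle_n",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "presets" in raw:
        kwargs["presets"] = tuple(raw["presets"])
    if "model_params" in raw:
        kwargs["model_params"] = ModelParams(**raw["model_params"])
    if "probe_cargoes" in raw:
        kwargs["probe_cargoes"] = tuple(
            _cargo_from_mapping(entry) for entry in raw["probe_cargoes"]
        )
    if "strains" in raw:
        kwargs["strains"] = tuple(StrainConfig(**entry) for entry in raw["strains"])
    for key in ("grid_R_av_nm", "grid_r_cargo_nm"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    return RunConfig(**kwargs)


def _cargo_from_mapping(entry: Mapping) -> CargoSpecies:
    mw = entry.get("mw_da", entry.get("mw"))
    if mw is not None and "mw_kda" in entry:
        raise InputError(f"cargo {entry.get('name')}: give mw_da or mw_kda, not both")
    if mw is None and "mw_kda" in entry:
        mw = float(entry["mw_kda"]) * 1000.0  # kDa -> Da at parse time
        log.info("cargo %s: converted %s kDa to %s Da", entry.get("name"), entry["mw_kda"], mw)
    return CargoSpecies(
        name=str(entry["name"]),
        mw=None if mw is None else float(mw),
        radius=None if entry.get("radius_nm") is None else float(entry["radius_nm"]),
        fraction=float(entry.get("fraction", 0.0)),
    )


def read_cargo_mix(path: str | Path) -> CargoMix:
    """Cargo mix from CSV (name, mw_da or radius_nm, fraction) or JSON/YAML."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        entries = df.to_dict("records")
        entries = [
            {k: (None if pd.isna(v) else v) for k, v in e.items()} for e in entries
        ]
    else:
        entries = yaml.safe_load(path.read_text())
    return CargoMix([_cargo_from_mapping(e) for e in entries])


def ingest_surfaces(
    path: str | Path,
    format: str | None = None,
    voxel_size: float | None = None,
) -> list[VesicleSurface]:
    """Read surfaces from a point-cloud CSV or one/many ASCII PLY files.

    Coordinates are assumed to be nm; pass ``voxel_size`` to scale voxel-unit
    CSV coordinates to nm.  Surfaces are grouped by vesicle_id; malformed
    rows are reported with line numbers.
    """
    import trimesh

    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "ply"
        elif path.suffix.lower() == ".ply":
            format = "ply"
        else:
            format = "csv"
    if format == "csv":
        if not path.is_file():
            raise InputError(f"no such point-cloud file: {path}")
        df = read_points_csv(path, voxel_size=voxel_size)
        if df.empty:
            raise InputError(f"point-cloud file {path} contains no rows")
        surfaces = []
        for vid, grp in df.groupby("vesicle_id", sort=False):
            pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
            surfaces.append(
                VesicleSurface(
                    vesicle_id=str(vid), points=pts, voxel_size=voxel_size or 0.0
                )
            )
        return surfaces
    if format == "ply":
        files = sorted(path.glob("*.ply")) if path.is_dir() else [path]
        if not files:
            raise InputError(f"no PLY files under {path}")
        surfaces = []
        for f in files:
            mesh = trimesh.load(f, file_type="ply", process=False)
            surfaces.append(
                VesicleSurface(
                    vesicle_id=f.stem,
                    points=np.asarray(mesh.vertices, dtype=float),
                    faces=np.asarray(mesh.faces, dtype=int),
                    voxel_size=voxel_size or 0.0,
                )
            )
        return surfaces
    raise InputError(f"unknown surface format {format!r} (expected csv or ply)")


def _write_tsv(df: pd.DataFrame, path: Path, meta: Mapping[str, object]) -> None:
    header = "".join(f"# {k} = {v}\n" for k, v in meta.items())
    body = df.to_csv(sep="\t", index=False, float_format="%.6g")
    path.write_text(header + body)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all tables plus a run manifest.

    Stages: strain generation, per-vesicle morphometry, per-strain summary,
    occupancy/partition model on the measured medians, K grid, and a
    Monte-Carlo spot check of the analytic K.  Returns the manifest dict.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        "simulate": child_seed(config.seed, 100),
        "bootstrap": child_seed(config.seed, 101),
        "oracle": child_seed(config.seed, 102),
    }

    # -- resolve strain configs up front so config errors precede compute
    strains: list[StrainConfig] = []
    presets = synthetic.builtin_strain_presets(
        n_vesicles=config.n_vesicles, seed=stage_seeds["simulate"]
    )
    by_name = {p.name: p for p in presets}
    for name in config.presets:
        if name not in by_name:
            raise InputError(
                f"unknown preset {name!r}; available: {', '.join(synthetic.PRESET_NAMES)}"
            )
        strains.append(by_name[name])
    strains.extend(config.strains)
    names = [s.name for s in strains]
    if config.reference_strain not in names:
        raise InputError(
            f"reference strain {config.reference_strain!r} not among strains {names}"
        )
    mixes = default_cargo_mixes()
    missing_mix = [n for n in names if n not in mixes]
    if missing_mix:
        raise InputError(f"no cargo mix defined for strain(s) {missing_mix}")

    # -- stage: simulate
    populations = {s.name: generate_strain(s) for s in strains}
    for s in strains:
        log.info("simulate: strain=%s vesicles=%d", s.name, len(populations[s.name]))
    meta_common = {"seed": config.seed, "reference_strain": config.reference_strain}
    all_surfaces = [v for pop in populations.values() for v in pop]
    synthetic.write_ground_truth_tsv(all_surfaces, out / "ground_truth.tsv")

    # -- stage: morphometry
    per_vesicle = measure_population(all_surfaces)
    _write_tsv(per_vesicle, out / "per_vesicle.tsv", meta_common)
    diam_summary = summarize_strains(
        per_vesicle,
        "max_diameter_nm",
        reference_strain=config.reference_strain,
        n_boot=config.n_boot,
        seed=stage_seeds["bootstrap"],
    )
    vol_summary = summarize_strains(
        per_vesicle,
        "volume_nm3",
        reference_strain=config.reference_strain,
        n_boot=config.n_boot,
        seed=stage_seeds["bootstrap"] + 1,
    )
    _write_tsv(
        diam_summary, out / "summary_max_diameter.tsv", {**meta_common, "units": "nm"}
    )
    _write_tsv(vol_summary, out / "summary_volume.tsv", {**meta_common, "units": "nm3"})
    log.info("morphometry: vesicles=%d strains=%d", len(per_vesicle), len(names))

    # -- stage: occupancy / partition model on measured median volumes
    radii = {
        row["strain"]: sphere_equivalent_radius(row["median"])
        for _, row in vol_summary.iterrows()
    }
    comparison = compare_strains(
        radii,
        mixes,
        config.probe_cargoes,
        params=config.model_params,
        reference=config.reference_strain,
        relaxed_ratio_threshold=config.relaxed_ratio_threshold,
    )
    model_meta = {
        **meta_common,
        "bilayer_thickness_nm": config.model_params.bilayer_thickness,
        "mw_radius_coefficient_nm_per_cbrt_da": config.model_params.mw_radius_coefficient,
        "relaxed_ratio_threshold": config.relaxed_ratio_threshold,
        "note": "vesicle radii are sphere-equivalent radii of measured median volumes",
    }
    _write_tsv(comparison.occupancy, out / "occupancy.tsv", model_meta)
    _write_tsv(comparison.partition, out / "partition.tsv", model_meta)

    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        return np.arange(lo, hi + 0.5 * step, step)

    grid = k_grid(
        _axis(*config.grid_R_av_nm),
        _axis(*config.grid_r_cargo_nm),
        relaxed_ratio_threshold=config.relaxed_ratio_threshold,
    )
    _write_tsv(grid.to_frame(), out / "k_grid.tsv", model_meta)
    log.info(
        "model: strains=%d probes=%d grid=%dx%d",
        len(radii),
        len(config.probe_cargoes),
        grid.r_cargo_axis.size,
        grid.R_av_axis.size,
    )
    log.warning(
        "WT median volume is an assumed model input; WT-referenced percent "
        "changes are model-assumption-dependent"
    )

    # -- stage: oracle spot check (analytic K vs Monte Carlo)
    spot_r, spot_R = 6.6, 13.2
    mc = mc_partition(spot_r, spot_R, n=config.oracle_n, seed=stage_seeds["oracle"])
    analytic = (1.0 - spot_r / spot_R) ** 3
    oracle_z = (mc.estimate - analytic) / mc.standard_error

    manifest = {
        "config": {
            "seed": config.seed,
            "presets": list(config.presets),
            "n_vesicles": config.n_vesicles,
            "reference_strain": config.reference_strain,
            "n_boot": config.n_boot,
            "bilayer_thickness_nm": config.model_params.bilayer_thickness,
            "mw_radius_coefficient": config.model_params.mw_radius_coefficient,
            "relaxed_ratio_threshold": config.relaxed_ratio_threshold,
        },
        "stage_seeds": stage_seeds,
        "strains": names,
        "n_vesicles_total": len(all_surfaces),
        "oracle_spot_check": {
            "r_cargo_nm": spot_r,
            "R_av_nm": spot_R,
            "analytic_K": analytic,
            "mc_K": mc.estimate,
            "z_score": oracle_z,
            "n": config.oracle_n,
        },
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "wall_clock_s": round(time.time() - t0, 3),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
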