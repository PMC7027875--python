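"""End-to-end pipeline driver: simulate -> preprocess -> calibrate -> map -> model.

`run_pipeline` chains every stage on a synthetic landscape, writes all
artefacts (rasters, crowns, cubes, calibration table, CV report,
coefficient tables, a human-readable report) under an output directory,
and records a manifest with content hashes and per-stage counts so a
rerun with the same configuration and seeds is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .inference import bootstrap_sar, classify_colimitation
from .plsr import LOG_TRAITS, cross_validate, fit_plsr, mosaic, predict_map
from .preprocess import (
    FilterConfig,
    average_bands,
    build_calibration_table,
    concat_tables,
    normalize_cube,
    resample_dialect,
    trim_bands,
)
from .synthetic import (
    GenerativeModel,
    SyntheticSpectraConfig,
    generate_crown_set,
    generate_landscape,
    simulate_spectra,
    simulate_trait_surface,
)
from .traitmodel import REFERENCE_COEFFICIENTS, TRAIT_NAMES

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


def _check_unknown(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Serializable configuration of every pipeline stage.

    Seeds are per stage; unknown keys in a loaded mapping are rejected.
    """

    # landscape / generative truth
    extent: tuple[int, int] = (40, 40)
    cell_size: float = 100.0
    seed_landscape: int = 101
    seed_traits: int = 202
    seed_crowns: int = 303
    seed_spectra: int = 404
    seed_bootstrap: int = 505
    sar_lambda: float = 0.4
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"N_pct": 0.12, "P_pct": 0.015, "NP_ratio": 1.2, "SLA_mm2_mg": 0.5}
    )
    n_crowns: int = 60
    n_flights: int = 2
    pixel_size: float = 10.0  # mapping flight lines
    calib_pixel_size: float = 4.0  # crown-matched calibration flight lines
    traits: tuple[str, ...] = TRAIT_NAMES
    # spectra noise
    brightness_sd: float = 0.08
    pixel_noise_sd: float = 0.004
    crown_effect_sd: float = 0.012
    # filters / PLSR / SAR
    filters: FilterConfig = field(default_factory=FilterConfig)
    max_components: int = 8
    cv_scheme: str = "LOTO"
    band: float = 2000.0
    n_boot: int = 50
    sample_size: int = 400

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        _check_unknown(d, {f.name for f in dataclasses.fields(cls)}, "pipeline config")
        if "filters" in d and isinstance(d["filters"], dict):
            _check_unknown(
                d["filters"], {f.name for f in dataclasses.fields(FilterConfig)}, "filters"
            )
            d["filters"] = FilterConfig(**d["filters"])
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        if "traits" in d:
            d["traits"] = tuple(d["traits"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["traits"] = list(self.traits)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str]  # relative path -> sha256
    counts: dict[str, dict]
    version: str = "0.1.0"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, dict] = {}

    # --- simulate ---------------------------------------------------------
    landscape = generate_landscape(config.extent, config.cell_size, config.seed_landscape)
    surfaces = {}
    for i, trait in enumerate(config.traits):
        gm = GenerativeModel(
            REFERENCE_COEFFICIENTS[trait],
            sar_lambda=config.sar_lambda,
            noise_sd=config.noise_sd.get(trait, 0.0),
        )
        surfaces[trait] = simulate_trait_surface(
            landscape, gm, seed=config.seed_traits + i, name=trait
        )
    crowns = generate_crown_set(
        landscape, config.n_crowns, surfaces, seed=config.seed_crowns
    )
    spectra_cfg = SyntheticSpectraConfig(
        brightness_sd=config.brightness_sd,
        pixel_noise_sd=config.pixel_noise_sd,
        crown_effect_sd=config.crown_effect_sd,
    )
    calib_cubes = []  # fine-pixel passes over the crown plots
    map_cubes = []  # full-coverage mapping flight lines
    for f in range(config.n_flights):
        dialect = "6nm" if f % 2 == 0 else "12nm"
        calib_cubes.append(
            simulate_spectra(
                crowns,
                spectra_cfg,
                dialect=dialect,
                seed=config.seed_spectra + f,
                landscape=landscape,
                trait_surfaces=surfaces,
                pixel_size=config.calib_pixel_size,
                flight_id=f"F{f + 1}",
                only_crown_neighborhoods=True,
            )
        )
        map_cubes.append(
            simulate_spectra(
                crowns,
                spectra_cfg,
                dialect=dialect,
                seed=config.seed_spectra + 1000 + f,
                landscape=landscape,
                trait_surfaces=surfaces,
                pixel_size=config.pixel_size,
                flight_id=f"F{f + 1}",
            )
        )
    outputs["elevation.asc"] = tio.write_raster(landscape.elevation, out / "elevation.asc")
    outputs["tch.asc"] = tio.write_raster(landscape.tch, out / "tch.asc")
    outputs["disturbance.asc"] = tio.write_raster(landscape.disturbance, out / "disturbance.asc")
    outputs["crowns.geojson"] = tio.write_crowns(crowns, out / "crowns.geojson")
    outputs["traits.csv"] = tio.write_trait_table(crowns.traits, out / "traits.csv")
    counts["simulate"] = {
        "cells": int(np.prod(config.extent)),
        "crowns": len(crowns),
        "flights": config.n_flights,
        "calib_pixels_per_flight": [c.n_pixels for c in calib_cubes],
        "map_pixels_per_flight": [c.n_pixels for c in map_cubes],
    }

    # --- preprocess -------------------------------------------------------
    # resampling targets the fine (6 nm) flight's averaged grid restricted to
    # the retained trim windows, so coarse flights never extrapolate at the
    # sensor edges (which trimming discards anyway)
    from .preprocess import _trim_mask

    fine_avg = average_bands(calib_cubes[0]).wavelengths
    target_grid = fine_avg[_trim_mask(fine_avg)]

    def process(cube):
        c = average_bands(cube)
        c = resample_dialect(c, target_grid)
        return normalize_cube(trim_bands(c))

    processed_calib = [process(c) for c in calib_cubes]
    processed_map = [process(c) for c in map_cubes]
    tables = [
        build_calibration_table(c, landscape.tch, crowns, filters=config.filters)
        for c in processed_calib
    ]
    table = concat_tables(tables)
    counts["preprocess"] = table.provenance["counts"]
    if table.n_rows == 0:
        raise RuntimeError("preprocess retained no pixels; cannot calibrate")

    # --- calibrate --------------------------------------------------------
    cv_rows = []
    models = {}
    for trait in config.traits:
        transform = "log" if trait in LOG_TRAITS else "identity"
        for scheme in ("LOPO", "LOTO"):
            cv = cross_validate(
                table, trait, scheme=scheme, max_components=config.max_components,
                transform=transform,
            )
            cv_rows.append(
                {
                    "scheme": scheme,
                    "trait": trait,
                    "n_components": cv.n_components,
                    "r2_pct": np.nan if cv.r2 is None else round(cv.r2, 1),
                    "pct_rmse": np.nan if cv.pct_rmse is None else round(cv.pct_rmse, 1),
                }
            )
            if scheme == config.cv_scheme:
                models[trait] = fit_plsr(table, trait, cv.n_components, transform)
    cv_report = pd.DataFrame(cv_rows)
    cv_path = out / "cv_report.csv"
    cv_report.to_csv(cv_path, index=False)
    outputs["cv_report.csv"] = cv_path
    counts["calibrate"] = {
        "rows": table.n_rows,
        "trees": table.n_trees,
        "chosen_components": {t: int(m.n_components) for t, m in models.items()},
    }

    # --- map --------------------------------------------------------------
    trait_rasters = {}
    for trait in config.traits:
        per_flight = [
            predict_map(models[trait], c, landscape.tch, grid=landscape.grid,
                        filters=config.filters)
            for c in processed_map
        ]
        trait_rasters[trait] = mosaic(per_flight)
        outputs[f"map_{trait}.asc"] = tio.write_raster(
            trait_rasters[trait].raster, out / f"map_{trait}.asc"
        )
    counts["map"] = {
        t: int(np.isfinite(tr.raster.values).sum()) for t, tr in trait_rasters.items()
    }

    # --- model ------------------------------------------------------------
    summaries = {}
    for i, trait in enumerate(config.traits):
        n_cells = int(np.isfinite(trait_rasters[trait].raster.values).sum())
        summ = bootstrap_sar(
            trait_rasters[trait],
            landscape,
            n_boot=config.n_boot,
            sample_size=min(config.sample_size, max(9, n_cells - 1)),
            seed=config.seed_bootstrap + i,
            band=config.band,
            trait=trait,
        )
        summaries[trait] = summ
        path = out / f"coefficients_{trait}.csv"
        summ.table().round(6).to_csv(path)
        outputs[f"coefficients_{trait}.csv"] = path
    counts["model"] = {
        t: {"n_boot": s.n_boot, "sample_size": s.sample_size, "failures": s.n_failures}
        for t, s in summaries.items()
    }

    # --- report -----------------------------------------------------------
    lines = ["Trait mapping pipeline report", "=" * 31, "", "Cross-validated model skill:", ""]
    lines.append(cv_report.to_string(index=False))
    lines.append("")
    for trait, summ in summaries.items():
        lines.append(f"Bootstrapped SAR coefficients - {trait}:")
        lines.append(summ.table().round(4).to_string())
        lines.append("")
    if "NP_ratio" in summaries:
        ref_np = float(summaries["NP_ratio"].mean[0])
        lines.append(
            f"Reference-stand N:P ratio {ref_np:.1f} -> {classify_colimitation(ref_np)}"
        )
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    outputs["report.txt"] = report_path

    config_path = config.to_yaml(out / "config.yaml")
    outputs["config.yaml"] = config_path

    manifest = RunManifest(
        config=config.to_dict(),
        outputs={name: _sha256(p) for name, p in sorted(outputs.items())},
        counts=counts,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
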