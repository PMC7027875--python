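"""Plain-text readers and writers for the pipeline's artefacts.

Formats are deliberately text-based and standard: single-band rasters as
ESRI ASCII grids, crown polygons as GeoJSON with tree_id and trait
properties, trait tables as CSV, and spectra cubes as a CSV pixel table
with a JSON wavelength sidecar.  Coordinates are cell/pixel centres in a
planar metric frame with the origin at the lower left.  Round-trips are
lossless to the written float precision (full repr precision here).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .crowns import CrownSet
from .cube import SpectraCube
from .grids import NODATA, Grid, Raster

__all__ = [
    "write_raster",
    "read_raster",
    "write_crowns",
    "read_crowns",
    "write_trait_table",
    "read_trait_table",
    "write_cube",
    "read_cube",
]


# --- rasters (ESRI ASCII grid) ---------------------------------------------


def write_raster(raster: Raster, path: str | Path) -> Path:
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, NODATA)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.origin[0]:.17g}\n"
        f"yllcorner {g.origin[1]:.17g}\n"
        f"cellsize {g.cell_size:.17g}\n"
        f"NODATA_value {NODATA:.17g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the top row first; our row 0 is the bottom row
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_raster(path: str | Path, name: str = "") -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    grid = Grid(
        shape=(int(header["nrows"]), int(header["ncols"])),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    vals = np.array(rows)[::-1]
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(grid, vals, name or path.stem)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# --- crowns (GeoJSON) -------------------------------------------------------


def write_crowns(crowns: CrownSet, path: str | Path) -> Path:
    path = Path(path)
    features = []
    for tid in crowns.tree_ids:
        props = {"tree_id": tid}
        props.update({k: float(v) for k, v in crowns.traits.loc[tid].items()})
        if crowns.deviations is not None:
            props["_deviations"] = {k: float(v) for k, v in crowns.deviations.loc[tid].items()}
        features.append(
            {"type": "Feature", "geometry": mapping(crowns.polygons[tid]), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_crowns(path: str | Path) -> CrownSet:
    with open(path) as fh:
        fc = json.load(fh)
    polygons, rows, devs = {}, [], []
    for feat in fc["features"]:
        props = dict(feat["properties"])
        tid = props.pop("tree_id")
        dev = props.pop("_deviations", None)
        polygons[tid] = shape(feat["geometry"])
        rows.append({"tree_id": tid, **props})
        if dev is not None:
            devs.append({"tree_id": tid, **dev})
    traits = pd.DataFrame(rows).set_index("tree_id")
    deviations = pd.DataFrame(devs).set_index("tree_id") if devs else None
    return CrownSet(polygons=polygons, traits=traits, deviations=deviations)


# --- trait tables (CSV) -----------------------------------------------------


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    traits.to_csv(path, float_format="%.12g")
    return path


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("tree_id")


# --- spectra cubes (CSV + JSON wavelength sidecar) --------------------------


def write_cube(cube: SpectraCube, path: str | Path) -> tuple[Path, Path]:
    """Write pixels to ``path`` (CSV) and metadata to ``path + '.json'``."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cols = {"x": cube.xy[:, 0], "y": cube.xy[:, 1]}
    for j in range(cube.n_bands):
        cols[f"b{j:04d}"] = cube.reflectance[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "wavelengths_nm": cube.wavelengths.tolist(),
        "pixel_size_m": cube.pixel_size,
        "flight_id": cube.flight_id,
        "solar_zenith_deg": cube.solar_zenith,
        "dialect": cube.dialect,
        "history": list(cube.history),
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)
    return path, sidecar


def read_cube(path: str | Path) -> SpectraCube:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    band_cols = [c for c in df.columns if c.startswith("b")]
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    if len(band_cols) != wavelengths.size:
        j = min(len(band_cols), wavelengths.size)
        raise ValueError(
            f"cube/sidecar band-count mismatch: {len(band_cols)} data bands vs "
            f"{wavelengths.size} wavelengths (first unmatched band index {j})"
        )
    return SpectraCube(
        wavelengths=wavelengths,
        reflectance=df[band_cols].to_numpy(dtype=float),
        xy=df[["x", "y"]].to_numpy(dtype=float),
        pixel_size=float(meta["pixel_size_m"]),
        flight_id=meta["flight_id"],
        solar_zenith=float(meta["solar_zenith_deg"]),
        dialect=meta["dialect"],
        history=tuple(meta.get("history", ())),
    )
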