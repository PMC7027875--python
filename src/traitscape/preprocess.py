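"""Spectral post-processing and crown-matched pixel filtering.

The processing chain mirrors standard airborne imaging-spectroscopy
practice: adjacent-band averaging to raise signal-to-noise (groups of 3
in the visible/NIR below 1,100 nm, groups of 2 in the SWIR), resampling
of coarse-bandwidth flight lines onto the fine wavelength grid, trimming
of detector edges and atmospheric water-absorption windows, and
brightness (L2) normalization so spectral shape rather than albedo
carries the signal.  Pixel filtering then matches spectra to field
crowns: sub-canopy pixels (height < 4 m), non-vegetation pixels
(NDVI < 0.75), high solar-zenith scenes, and pixels covering less than
80% of a crown are excluded, in that order, with per-stage counts kept
as provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree, box

from .crowns import CrownSet
from .cube import SpectraCube
from .grids import Raster

__all__ = [
    "FilterConfig",
    "CalibrationTable",
    "average_bands",
    "resample_dialect",
    "trim_bands",
    "brightness_normalize",
    "normalize_cube",
    "compute_ndvi",
    "build_calibration_table",
    "concat_tables",
    "TRIM_KEEP_RANGE",
    "TRIM_EXCLUDE_WINDOWS",
]

#: Retained wavelength range (closed) and excluded windows (open intervals):
#: spectrometer edges, the detector-overlap region and water-absorption bands.
TRIM_KEEP_RANGE = (420.0, 2400.0)
TRIM_EXCLUDE_WINDOWS = ((900.0, 1000.0), (1350.0, 1480.0), (1780.0, 2032.0))

#: Band-averaging regions: (lower bound nm, upper bound nm, group size).
AVERAGE_REGIONS = ((-np.inf, 1100.0, 3), (1100.0, np.inf, 2))


def average_bands(cube: SpectraCube) -> SpectraCube:
    """Average consecutive band groups: 3 below 1,100 nm, 2 at and above.

    Trailing incomplete groups are averaged as-is, conserving spectral
    coverage.  A region with fewer bands than one full group is passed
    through with a warning.
    """
    w = cube.wavelengths
    new_w: list[float] = []
    new_r: list[np.ndarray] = []
    for lo, hi, size in AVERAGE_REGIONS:
        sel = np.nonzero((w >= lo) & (w < hi))[0]
        if sel.size == 0:
            continue
        if sel.size < size:
            warnings.warn(
                f"spectral region [{lo}, {hi}) has only {sel.size} band(s); "
                "passed through unaveraged",
                stacklevel=2,
            )
            new_w.extend(w[sel])
            new_r.extend(cube.reflectance[:, j] for j in sel)
            continue
        for start in range(0, sel.size, size):
            grp = sel[start:start + size]
            new_w.append(float(w[grp].mean()))
            new_r.append(cube.reflectance[:, grp].mean(axis=1))
    return cube.with_bands(np.array(new_w), np.column_stack(new_r), "average_bands")


def resample_dialect(cube: SpectraCube, target_wavelengths: np.ndarray) -> SpectraCube:
    """Piecewise-linear interpolation of every spectrum onto ``target_wavelengths``.

    Coarse (12 nm) flight lines are brought onto the fine (6 nm) grid this
    way; a cube already on the target grid passes through unchanged.
    Extrapolation beyond the source range is rejected.
    """
    target = np.asarray(target_wavelengths, dtype=float)
    if np.any(np.diff(target) <= 0):
        raise ValueError("target wavelengths must be strictly increasing")
    w = cube.wavelengths
    if target.size == w.size and np.allclose(target, w):
        return cube.with_bands(w, cube.reflectance.copy(), "resample_dialect", dialect="6nm")
    if target[0] < w[0] or target[-1] > w[-1]:
        raise ValueError(
            f"resampling would extrapolate: target range [{target[0]}, {target[-1]}] "
            f"exceeds source range [{w[0]}, {w[-1]}]"
        )
    out = np.empty((cube.n_pixels, target.size))
    for i in range(cube.n_pixels):
        out[i] = np.interp(target, w, cube.reflectance[i])
    return cube.with_bands(target, out, "resample_dialect", dialect="6nm")


def _trim_mask(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    keep = (w >= TRIM_KEEP_RANGE[0]) & (w <= TRIM_KEEP_RANGE[1])
    for lo, hi in TRIM_EXCLUDE_WINDOWS:
        keep &= ~((w > lo) & (w < hi))  # open exclusion: boundary bands retained
    return keep


def trim_bands(cube: SpectraCube) -> SpectraCube:
    """Drop detector-edge and water-absorption bands; band order preserved."""
    keep = _trim_mask(cube.wavelengths)
    if not keep.any():
        raise ValueError("trimming removed every band: wavelength grid outside retained windows")
    return cube.with_bands(cube.wavelengths[keep], cube.reflectance[:, keep], "trim_bands")


def brightness_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide a spectrum (or each row of a matrix) by its Euclidean norm."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim == 1:
        norm = np.linalg.norm(x)
        if norm == 0:
            raise ValueError("cannot brightness-normalize an all-zero spectrum")
        return x / norm
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = np.nonzero(norms.ravel() == 0)[0]
        raise ValueError(f"cannot brightness-normalize all-zero spectra at rows {bad.tolist()}")
    return x / norms


def normalize_cube(cube: SpectraCube) -> SpectraCube:
    """Brightness-normalize every pixel spectrum of a cube."""
    return cube.with_bands(
        cube.wavelengths, brightness_normalize(cube.reflectance), "brightness_normalize"
    )


def compute_ndvi(
    spectrum: np.ndarray, wavelengths: np.ndarray, red: float = 650.0, nir: float = 860.0
) -> np.ndarray | float:
    """NDVI = (NIR - Red)/(NIR + Red) using the nearest available bands.

    Scale-invariant, so it may be computed before or after brightness
    normalization.  A zero denominator yields NaN (flagged, never raised),
    so the affected pixel can be excluded downstream.
    """
    w = np.asarray(wavelengths, dtype=float)
    i_red = int(np.argmin(np.abs(w - red)))
    i_nir = int(np.argmin(np.abs(w - nir)))
    x = np.asarray(spectrum, dtype=float)
    r = x[..., i_red]
    n = x[..., i_nir]
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (n - r) / np.where(denom != 0, denom, 1.0), np.nan)
    return float(ndvi) if np.ndim(ndvi) == 0 else ndvi


@dataclass(frozen=True)
class FilterConfig:
    """Pixel-retention thresholds for crown matching."""

    min_height: float = 4.0  # m
    min_ndvi: float = 0.75
    zenith_threshold: float = 50.0  # degrees
    zenith_rule: str = "exclude_above"  # or "include_above" (the literal reading)
    min_crown_coverage: float = 0.80  # fraction of the pixel inside the crown
    red_nm: float = 650.0
    nir_nm: float = 860.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_crown_coverage <= 1.0:
            raise ValueError("min_crown_coverage must be a fraction in [0, 1]")
        if self.zenith_rule not in ("exclude_above", "include_above"):
            raise ValueError("zenith_rule must be 'exclude_above' or 'include_above'")
        for v in (self.min_height, self.min_ndvi, self.zenith_threshold):
            if not np.isfinite(v) and not np.isneginf(v):
                raise ValueError("filter thresholds must be finite (or -inf to disable)")

    def zenith_passes(self, solar_zenith: float) -> bool:
        if self.zenith_rule == "exclude_above":
            return solar_zenith <= self.zenith_threshold
        return solar_zenith > self.zenith_threshold


@dataclass
class CalibrationTable:
    """Filtered pixel spectra matched to tree traits — the X/y matrix.

    ``spectra`` rows share one wavelength grid; ``meta`` carries
    tree_id, flight_id and pixel coordinates per row; ``traits`` the
    measured trait values per row; ``provenance`` the per-stage
    exclusion counts and the processing history of the source cube.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame
    traits: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != len(self.meta) or len(self.meta) != len(self.traits):
            raise ValueError("spectra, meta and traits must have matching row counts")
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("spectra must be (n_rows, n_bands)")

    @property
    def n_rows(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_trees(self) -> int:
        return self.meta["tree_id"].nunique()

    def rows_for_trait(self, trait: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, groups) for one trait, dropping rows with missing values."""
        y = self.traits[trait].to_numpy(dtype=float)
        ok = np.isfinite(y)
        return self.spectra[ok], y[ok], self.meta["tree_id"].to_numpy()[ok]


def build_calibration_table(
    cube: SpectraCube,
    chm: Raster,
    crowns: CrownSet,
    traits: pd.DataFrame | None = None,
    filters: FilterConfig | None = None,
) -> CalibrationTable:
    """Filter cube pixels and match survivors to crowns.

    Stages run in order: canopy height >= ``min_height``; NDVI >=
    ``min_ndvi``; solar-zenith rule; crown coverage >=
    ``min_crown_coverage``.  A pixel covered sufficiently by several
    crowns is assigned to the crown with the larger coverage, ties
    broken by larger crown area then lower tree_id, so output is
    deterministic.  An empty result is returned with full provenance
    (model fitting refuses it later).
    """
    cfg = filters or FilterConfig()
    trait_table = crowns.traits if traits is None else traits
    n0 = cube.n_pixels
    counts = {"input": n0}

    alive = np.ones(n0, dtype=bool)

    heights = chm.sample(cube.xy[:, 0], cube.xy[:, 1])
    fail = alive & ~(heights >= cfg.min_height)
    counts["excluded_height"] = int(fail.sum())
    alive &= ~fail

    ndvi = compute_ndvi(cube.reflectance, cube.wavelengths, cfg.red_nm, cfg.nir_nm)
    fail = alive & ~(np.nan_to_num(ndvi, nan=-np.inf) >= cfg.min_ndvi)
    counts["excluded_ndvi"] = int(fail.sum())
    alive &= ~fail

    if not cfg.zenith_passes(cube.solar_zenith):
        counts["excluded_zenith"] = int(alive.sum())
        alive &= False
    else:
        counts["excluded_zenith"] = 0

    # crown coverage: fraction of the pixel square inside each candidate crown
    ids = crowns.tree_ids
    geoms = [crowns.polygons[t] for t in ids]
    strtree = STRtree(geoms)
    half = cube.pixel_size / 2.0
    pixel_area = cube.pixel_size**2
    assigned = np.full(n0, -1)
    cand_pix = np.nonzero(alive)[0]
    if cand_pix.size:
        squares = [box(x - half, y - half, x + half, y + half) for x, y in cube.xy[cand_pix]]
        qi, qj = strtree.query(squares, predicate="intersects")
        best: dict[int, tuple[float, float, str]] = {}
        for si, cj in zip(qi, qj):
            pix = int(cand_pix[si])
            cov = squares[si].intersection(geoms[cj]).area / pixel_area
            if cov < cfg.min_crown_coverage:
                continue
            # rank: larger coverage, then larger crown area, then lower tree_id
            key = (-cov, -geoms[cj].area, ids[cj])
            if pix not in best or key < best[pix][0:3]:
                best[pix] = (key[0], key[1], key[2], int(cj))
        for pix, (_, _, _, cj) in best.items():
            assigned[pix] = cj
    fail = alive & (assigned < 0)
    counts["excluded_coverage"] = int(fail.sum())
    alive &= ~fail
    counts["retained"] = int(alive.sum())

    sel = np.nonzero(alive)[0]
    tree_ids = [ids[assigned[i]] for i in sel]
    meta = pd.DataFrame(
        {
            "tree_id": tree_ids,
            "flight_id": cube.flight_id,
            "x": cube.xy[sel, 0],
            "y": cube.xy[sel, 1],
        }
    )
    trait_rows = trait_table.reindex(tree_ids).reset_index(drop=True)
    provenance = {
        "counts": counts,
        "filter_config": {
            "min_height": cfg.min_height,
            "min_ndvi": cfg.min_ndvi,
            "zenith_threshold": cfg.zenith_threshold,
            "zenith_rule": cfg.zenith_rule,
            "min_crown_coverage": cfg.min_crown_coverage,
            "red_nm": cfg.red_nm,
            "nir_nm": cfg.nir_nm,
        },
        "pipeline": list(cube.history),
        "flight_id": cube.flight_id,
    }
    return CalibrationTable(
        spectra=cube.reflectance[sel],
        wavelengths=cube.wavelengths.copy(),
        meta=meta,
        traits=trait_rows,
        provenance=provenance,
    )


def concat_tables(tables: list[CalibrationTable]) -> CalibrationTable:
    """Stack calibration tables from several flight lines (shared grid required)."""
    if not tables:
        raise ValueError("no tables to concatenate")
    w0 = tables[0].wavelengths
    for t in tables[1:]:
        if t.wavelengths.size != w0.size or not np.allclose(t.wavelengths, w0):
            raise ValueError("calibration tables are on different wavelength grids")
        if t.provenance.get("pipeline") != tables[0].provenance.get("pipeline"):
            raise ValueError("calibration tables were processed with different pipelines")
    return CalibrationTable(
        spectra=np.vstack([t.spectra for t in tables]),
        wavelengths=w0.copy(),
        meta=pd.concat([t.meta for t in tables], ignore_index=True),
        traits=pd.concat([t.traits for t in tables], ignore_index=True),
        provenance={
            "counts": {
                k: sum(t.provenance["counts"][k] for t in tables)
                for k in tables[0].provenance["counts"]
            },
            "filter_config": tables[0].provenance["filter_config"],
            "pipeline": tables[0].provenance["pipeline"],
            "flight_id": [t.provenance.get("flight_id") for t in tables],
        },
    )
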