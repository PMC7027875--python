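"""Shared fixtures: one small synthetic campaign reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import traitscape as ts
from traitscape.grids import Grid, Raster
from traitscape.preprocess import (
    CalibrationTable,
    _trim_mask,
    average_bands,
    normalize_cube,
    resample_dialect,
    trim_bands,
)

NOISE_SD = {"N_pct": 0.12, "P_pct": 0.015, "NP_ratio": 1.2, "SLA_mm2_mg": 0.5}


@pytest.fixture(scope="session")
def landscape():
    return ts.generate_landscape((20, 20), 100.0, seed=7)


@pytest.fixture(scope="session")
def surfaces(landscape):
    out = {}
    for trait in ts.TRAIT_NAMES:
        gm = ts.GenerativeModel(
            ts.REFERENCE_COEFFICIENTS[trait], sar_lambda=0.3, noise_sd=NOISE_SD[trait]
        )
        out[trait] = ts.simulate_trait_surface(landscape, gm, seed=11, name=trait)
    return out


@pytest.fixture(scope="session")
def crowns(landscape, surfaces):
    return ts.generate_crown_set(landscape, 40, surfaces, seed=3)


def process_chain(cube, target_grid=None):
    """Reference processing order: average -> resample -> trim -> normalize."""
    c = average_bands(cube)
    if target_grid is None:
        target_grid = c.wavelengths[_trim_mask(c.wavelengths)]
    c = resample_dialect(c, target_grid)
    return normalize_cube(trim_bands(c))


@pytest.fixture(scope="session")
def calib_table(landscape, surfaces, crowns):
    """Two-flight (6 nm + 12 nm) calibration table over the crown plots."""
    cubes = [
        ts.simulate_spectra(
            crowns, dialect=d, seed=5 + i, landscape=landscape, trait_surfaces=surfaces,
            pixel_size=4.0, flight_id=f"F{i + 1}", only_crown_neighborhoods=True,
        )
        for i, d in enumerate(("6nm", "12nm"))
    ]
    fa = average_bands(cubes[0]).wavelengths
    target = fa[_trim_mask(fa)]
    processed = [process_chain(c, target) for c in cubes]
    return ts.concat_tables(
        [ts.build_calibration_table(c, landscape.tch, crowns) for c in processed]
    )


@pytest.fixture
def flat_landscape():
    """Constant reference-stand landscape: elevation 200 m, TCH 30 m, old-growth."""
    grid = Grid((12, 12), 100.0)
    return ts.LandscapeRasters(
        elevation=Raster(grid, np.full(grid.shape, 200.0), "elevation"),
        tch=Raster(grid, np.full(grid.shape, 30.0), "tch"),
        disturbance=Raster(grid, np.zeros(grid.shape), "disturbance"),
    )


def clustered_noise_table(seed, n_trees=15, px=5, bands=30, crown_sd=0.5, pix_sd=0.02):
    """Calibration table with strong within-crown shared spectral noise.

    Spectra respond linearly to a single absorption feature; every pixel
    of a tree shares one spectral deviation vector, so holding out
    pixels (LOPO) leaks crown structure that holding out trees (LOTO)
    does not.
    """
    rng = np.random.default_rng(seed)
    w = np.linspace(1000, 1600, bands)
    trait = rng.uniform(1.0, 3.0, n_trees)
    profile = np.exp(-((w - 1300.0) ** 2) / (2 * 80.0**2))
    rows, ys, ids = [], [], []
    for t in range(n_trees):
        shared = rng.normal(0, crown_sd, bands)
        for _ in range(px):
            rows.append(1.0 - 0.1 * trait[t] * profile + shared + rng.normal(0, pix_sd, bands))
            ys.append(trait[t])
            ids.append(f"T{t:03d}")
    meta = pd.DataFrame({"tree_id": ids, "flight_id": "F1", "x": 0.0, "y": 0.0})
    return CalibrationTable(
        np.array(rows), w, meta, pd.DataFrame({"N_pct": ys}), {"counts": {}, "pipeline": []}
    )
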