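"""Crown-matched PLSR calibration, cross-validation and trait mapping.

Simulates two flight lines (6 nm and 12 nm bandwidth dialects) over a
synthetic landscape, runs the spectral post-processing chain
(band averaging -> dialect resampling -> trimming -> brightness
normalization), filters pixels against the crown polygons, fits PLSR
trait models with leave-one-pixel-out (LOPO) and leave-one-tree-out
(LOTO) cross-validation, and maps the trait to a 1-ha raster.
"""

import numpy as np

import traitscape as ts
from traitscape.preprocess import (
    _trim_mask,
    average_bands,
    normalize_cube,
    resample_dialect,
    trim_bands,
)

landscape = ts.generate_landscape((20, 20), 100.0, seed=7)
model = ts.GenerativeModel(ts.REFERENCE_COEFFICIENTS["N_pct"], sar_lambda=0.3, noise_sd=0.12)
surface = ts.simulate_trait_surface(landscape, model, seed=11, name="N_pct")
crowns = ts.generate_crown_set(landscape, 40, {"N_pct": surface}, seed=3)

spectra_cfg = ts.SyntheticSpectraConfig(features={"N_pct": (1510.0, 40.0, 0.04)})
cubes = [
    ts.simulate_spectra(
        crowns, spectra_cfg, dialect=d, seed=5 + i, landscape=landscape,
        trait_surfaces={"N_pct": surface}, pixel_size=4.0,
        flight_id=f"F{i + 1}", only_crown_neighborhoods=True,
    )
    for i, d in enumerate(("6nm", "12nm"))
]

fine = average_bands(cubes[0]).wavelengths
target = fine[_trim_mask(fine)]
processed = [
    normalize_cube(trim_bands(resample_dialect(average_bands(c), target))) for c in cubes
]
table = ts.concat_tables(
    [ts.build_calibration_table(c, landscape.tch, crowns) for c in processed]
)
counts = table.provenance["counts"]
print(f"pixel filtering: {counts['input']} pixels -> {counts['retained']} retained")
print(f"  excluded: height {counts['excluded_height']}, NDVI {counts['excluded_ndvi']}, "
      f"coverage {counts['excluded_coverage']}")
print(f"calibration table: {table.n_rows} spectra of {table.n_trees} trees, "
      f"{table.wavelengths.size} bands\n")

for scheme in ("LOPO", "LOTO"):
    cv = ts.cross_validate(table, "N_pct", scheme=scheme, max_components=8)
    print(f"{scheme}: {cv.n_components} components, R2 {cv.r2:.1f}%, %RMSE {cv.pct_rmse:.1f}")
# LOPO leaks within-crown structure into training and reads higher than the
# honest tree-held-out LOTO figure.

cv = ts.cross_validate(table, "N_pct", scheme="LOTO", max_components=8)
plsr = ts.fit_plsr(table, "N_pct", cv.n_components, transform="log")
flight = ts.simulate_spectra(
    crowns, spectra_cfg, seed=20, landscape=landscape,
    trait_surfaces={"N_pct": surface}, pixel_size=10.0,
)
mapped = ts.predict_map(
    plsr, normalize_cube(trim_bands(resample_dialect(average_bands(flight), target))),
    landscape.tch, grid=landscape.grid,
)
ok = np.isfinite(mapped.raster.values)
r = np.corrcoef(mapped.raster.values[ok], surface.values[ok])[0, 1]
print(f"\n1-ha trait map: {ok.sum()} cells, correlation with generative surface r = {r:.2f}")
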