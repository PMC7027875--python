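"""Synthetic landscapes, crowns, trait surfaces and reflectance cubes.

This module generates desk-scale stand-ins for an airborne campaign over
a logged tropical-forest landscape, with the statistical structure the
downstream analysis assumes:

* smooth (spatially autocorrelated) elevation and canopy-height fields,
  with disturbance history assigned in contiguous blocks, mimicking a
  mosaic of old-growth reserves and logged coupes;
* trait surfaces that follow the linear disturbance x elevation x TCH
  model with simultaneous-autoregressive (SAR) error;
* crown polygons whose trees carry the local trait value plus a
  tree-level deviation;
* reflectance spectra in which each trait subtracts a Gaussian
  absorption feature from a vegetation baseline, with multiplicative
  brightness variation, a shared within-crown offset and per-pixel
  noise.  The trait->spectrum link is linear by construction, so
  chemometric recovery is testable exactly.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import splu
from shapely.geometry import Point

from .crowns import CrownSet
from .cube import SpectraCube
from .grids import Grid, Raster
from .traitmodel import TraitModel

__all__ = [
    "LandscapeConfig",
    "LandscapeRasters",
    "GenerativeModel",
    "CrownConfig",
    "SyntheticSpectraConfig",
    "generate_landscape",
    "simulate_trait_surface",
    "generate_crown_set",
    "simulate_spectra",
    "rook_weights",
    "sar_error_field",
]


# ---------------------------------------------------------------------------
# landscape


@dataclass(frozen=True)
class LandscapeConfig:
    """Shape parameters of the synthetic landscape fields.

    Elevation and TCH are smoothed white-noise fields (Gaussian kernel,
    widths in cells); ``elevation_amplitude`` scales relief around the
    mid-point of ``elevation_range`` (0 gives a perfectly flat terrain).
    Disturbance thresholds a third smooth field at the ``logged_fraction``
    quantile, producing contiguous logged blocks; logged stands lose
    ``tch_logged_deficit`` metres of canopy height on average.
    """

    elevation_range: tuple[float, float] = (100.0, 1000.0)
    elevation_amplitude: float = 1.0
    elevation_sigma: float = 5.0  # cells
    tch_mean: float = 27.0  # m
    tch_sd: float = 9.0  # m
    tch_sigma: float = 3.0  # cells
    tch_logged_deficit: float = 8.0  # m
    logged_fraction: float = 0.5
    disturbance_sigma: float = 6.0  # cells

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range
        if not (0 < lo < hi):
            raise ValueError(f"elevation range must be positive and increasing, got {self.elevation_range}")
        if self.elevation_amplitude < 0 or self.tch_sd < 0:
            raise ValueError("field amplitudes must be non-negative")
        if not 0 < self.logged_fraction < 1:
            raise ValueError("logged_fraction must be in (0, 1)")


@dataclass
class LandscapeRasters:
    """Elevation (m a.s.l.), TCH (m) and disturbance class on one grid."""

    elevation: Raster
    tch: Raster
    disturbance: Raster  # 0 = old-growth, 1 = logged

    def __post_init__(self) -> None:
        g = self.elevation.grid
        if self.tch.grid != g or self.disturbance.grid != g:
            raise ValueError("all landscape rasters must share one grid")
        d = self.disturbance.values
        if not np.isin(d[np.isfinite(d)], (0.0, 1.0)).all():
            raise ValueError("disturbance must be two-valued (0/1)")
        if np.nanmin(self.tch.values) < 0:
            raise ValueError("TCH must be non-negative")

    @property
    def grid(self) -> Grid:
        return self.elevation.grid


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to zero mean / unit SD."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / sd if sd > 0 else np.zeros(shape)


def generate_landscape(
    extent: tuple[int, int] = (60, 60),
    cell_size: float = 100.0,
    seed: int = 0,
    config: LandscapeConfig | None = None,
) -> LandscapeRasters:
    """Generate elevation/TCH/disturbance rasters on an ``extent`` cell grid."""
    nrows, ncols = extent
    if nrows < 10 or ncols < 10:
        raise ValueError(f"extent must be at least 10x10 cells, got {extent}")
    if cell_size <= 0:
        raise ValueError(f"cell size must be positive, got {cell_size}")
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    grid = Grid(shape=(nrows, ncols), cell_size=cell_size)

    lo, hi = cfg.elevation_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    z = _smooth_unit_field(rng, extent, cfg.elevation_sigma)
    # +/-3 SD of the smooth field spans the configured range; clip guards the tails
    elevation = np.clip(mid + cfg.elevation_amplitude * (half / 3.0) * z, lo, hi)

    z_d = _smooth_unit_field(rng, extent, cfg.disturbance_sigma)
    logged = (z_d < np.quantile(z_d, cfg.logged_fraction)).astype(float)

    z_t = _smooth_unit_field(rng, extent, cfg.tch_sigma)
    tch = np.clip(cfg.tch_mean + cfg.tch_sd * z_t - cfg.tch_logged_deficit * logged, 0.0, None)

    return LandscapeRasters(
        elevation=Raster(grid, elevation, "elevation"),
        tch=Raster(grid, tch, "tch"),
        disturbance=Raster(grid, logged, "disturbance"),
    )


# ---------------------------------------------------------------------------
# trait surfaces


@dataclass(frozen=True)
class GenerativeModel(TraitModel):
    """Trait model plus the SAR error process used to simulate surfaces.

    The error field solves ``u = lambda W u + eps`` with ``W`` the
    row-standardized first-order (rook) neighbourhood of the grid and
    ``eps`` i.i.d. normal with SD ``noise_sd``.
    """

    sar_lambda: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.sar_lambda < 1.0:
            raise ValueError(
                f"sar_lambda must be in [0, 1); got {self.sar_lambda} "
                "(the error process I - lambda W is not invertible at lambda >= 1)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def rook_weights(shape: tuple[int, int], row_standardize: bool = True) -> sparse.csr_matrix:
    """First-order (rook) neighbourhood weights on a grid, row-major cell order."""
    nrows, ncols = shape
    idx = np.arange(nrows * ncols).reshape(shape)
    rows, cols = [], []
    for di, dj in ((0, 1), (1, 0)):
        a = idx[: nrows - di, : ncols - dj].ravel()
        b = idx[di:, dj:].ravel()
        rows.extend([a, b])
        cols.extend([b, a])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    W = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(nrows * ncols, nrows * ncols)
    )
    if row_standardize:
        deg = np.asarray(W.sum(axis=1)).ravel()
        W = sparse.diags(1.0 / deg) @ W
    return W.tocsr()


def sar_error_field(
    shape: tuple[int, int], lam: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw u solving u = lam W u + eps on a grid (rook W, row-standardized)."""
    eps = rng.normal(0.0, noise_sd, size=shape).ravel()
    if lam == 0.0 or noise_sd == 0.0:
        return eps.reshape(shape)
    n = eps.size
    A = (sparse.eye(n, format="csc") - lam * rook_weights(shape).tocsc())
    return splu(A).solve(eps).reshape(shape)


def simulate_trait_surface(
    landscape: LandscapeRasters, model: GenerativeModel, seed: int = 0, name: str = "trait"
) -> Raster:
    """Trait raster = linear predictor on standardized covariates + SAR error."""
    lp = model.linear_predictor(
        landscape.disturbance.values.ravel(),
        landscape.elevation.values.ravel(),
        landscape.tch.values.ravel(),
    ).reshape(landscape.grid.shape)
    u = sar_error_field(
        landscape.grid.shape, model.sar_lambda, model.noise_sd, np.random.default_rng(seed)
    )
    return Raster(landscape.grid, lp + u, name)


# ---------------------------------------------------------------------------
# crowns


@dataclass(frozen=True)
class CrownConfig:
    """Crown placement and tree-level trait sampling.

    ``deviation_sd`` maps trait name -> SD of the normal tree-level
    deviation added to the local surface value.  ``overlap_fraction`` of
    crowns are deliberately placed overlapping an earlier crown;
    ``short_fraction`` are centred on the lowest-TCH decile of the
    landscape so some pixels fall over sub-canopy vegetation and
    exercise the height filter.
    """

    radius_range: tuple[float, float] = (4.0, 8.0)  # m
    deviation_sd: dict[str, float] = field(
        default_factory=lambda: {
            "N_pct": 0.15, "P_pct": 0.012, "NP_ratio": 1.0, "SLA_mm2_mg": 0.8
        }
    )
    overlap_fraction: float = 0.0
    short_fraction: float = 0.0
    max_tries: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError("radius_range must be positive and ordered")
        for frac in (self.overlap_fraction, self.short_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def generate_crown_set(
    landscape: LandscapeRasters,
    n_crowns: int,
    trait_surfaces: dict[str, Raster],
    seed: int = 0,
    config: CrownConfig | None = None,
) -> CrownSet:
    """Place crown polygons and sample their true traits from the surfaces."""
    if n_crowns < 1:
        raise ValueError("n_crowns must be at least 1")
    cfg = config or CrownConfig()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landscape.grid.extent
    rmax = cfg.radius_range[1]

    short_cells = None
    if cfg.short_fraction > 0:
        tch = landscape.tch.values
        thresh = np.quantile(tch, 0.10)
        rr, cc = np.nonzero(tch <= thresh)
        short_cells = np.column_stack([rr, cc])

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    n_overlap = int(round(cfg.overlap_fraction * n_crowns))
    n_short = int(round(cfg.short_fraction * n_crowns))
    for i in range(n_crowns):
        radius = rng.uniform(*cfg.radius_range)
        want_overlap = i > 0 and i < n_overlap + 1 and n_overlap > 0
        placed = False
        for _ in range(cfg.max_tries):
            if want_overlap:
                cx, cy = centers[int(rng.integers(len(centers)))]
                ang = rng.uniform(0, 2 * math.pi)
                d = rng.uniform(0.2, 0.8) * (radius + radii[0])
                x, y = cx + d * math.cos(ang), cy + d * math.sin(ang)
            elif short_cells is not None and i >= n_crowns - n_short:
                r_, c_ = short_cells[int(rng.integers(len(short_cells)))]
                h = landscape.grid.cell_size
                x = xmin + (c_ + rng.uniform(0.25, 0.75)) * h
                y = ymin + (r_ + rng.uniform(0.25, 0.75)) * h
            else:
                x = rng.uniform(xmin + rmax, xmax - rmax)
                y = rng.uniform(ymin + rmax, ymax - rmax)
            if not (xmin <= x - radius and x + radius <= xmax and ymin <= y - radius and y + radius <= ymax):
                continue
            if not want_overlap and any(
                (x - cx) ** 2 + (y - cy) ** 2 < (radius + r0) ** 2
                for (cx, cy), r0 in zip(centers, radii)
            ):
                continue
            centers.append((x, y))
            radii.append(radius)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place crown {i + 1} of {n_crowns}: placement capacity exceeded"
            )

    polygons = {}
    rows = []
    devs = []
    for i, ((x, y), radius) in enumerate(zip(centers, radii)):
        tid = f"T{i:04d}"
        polygons[tid] = Point(x, y).buffer(radius, quad_segs=8)
        rec, dev = {"tree_id": tid}, {"tree_id": tid}
        for trait, surf in trait_surfaces.items():
            d = rng.normal(0.0, cfg.deviation_sd.get(trait, 0.0))
            rec[trait] = float(surf.sample(x, y)) + d
            dev[trait] = d
        rows.append(rec)
        devs.append(dev)
    traits = pd.DataFrame(rows).set_index("tree_id")
    deviations = pd.DataFrame(devs).set_index("tree_id")
    return CrownSet(polygons=polygons, traits=traits, deviations=deviations)


# ---------------------------------------------------------------------------
# spectra


def _vegetation_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth green-vegetation reflectance curve (chlorophyll trough, red
    edge, NIR plateau, water-dominated SWIR)."""
    anchors_w = np.array([380, 420, 550, 680, 750, 1100, 1300, 1450, 1650, 1900, 2100, 2400, 2500])
    anchors_r = np.array([0.03, 0.03, 0.06, 0.03, 0.45, 0.48, 0.45, 0.25, 0.30, 0.12, 0.18, 0.08, 0.06])
    return np.interp(wavelengths, anchors_w, anchors_r)


def _soil_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Bright, spectrally flat soil/litter curve; NDVI well below 0.75."""
    return 0.15 + 0.20 * (wavelengths - 380.0) / (2500.0 - 380.0)


@dataclass(frozen=True)
class SyntheticSpectraConfig:
    """Trait-linked reflectance simulation parameters.

    ``features`` maps trait name -> (centre nm, width nm, depth per unit
    trait): each trait subtracts ``depth * trait * exp(-(w-c)^2/(2 width^2))``
    from the baseline, so reflectance at a feature centre is linear in
    the trait.  Brightness variation is multiplicative on a log scale;
    the within-crown deviation is one shared offset per crown; pixel
    noise is i.i.d. per band.
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(380.0, 2500.0 + 1e-9, 6.0)
    )
    features: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "N_pct": (1510.0, 40.0, 0.040),
            "P_pct": (1680.0, 40.0, 0.350),
            "NP_ratio": (2210.0, 50.0, 0.004),
            "SLA_mm2_mg": (1240.0, 50.0, 0.004),
        }
    )
    brightness_sd: float = 0.10  # log-scale multiplicative SD
    pixel_noise_sd: float = 0.010  # additive reflectance SD
    crown_effect_sd: float = 0.015  # shared within-crown offset SD

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        for sd in (self.brightness_sd, self.pixel_noise_sd, self.crown_effect_sd):
            if sd < 0:
                raise ValueError("all noise SDs must be non-negative")
        for trait, (center, width, _depth) in self.features.items():
            if not (w[0] <= center <= w[-1]):
                raise ValueError(
                    f"absorption feature for {trait!r} at {center} nm lies outside "
                    f"the wavelength grid [{w[0]}, {w[-1]}]"
                )
            if width <= 0:
                raise ValueError(f"feature width for {trait!r} must be positive")


def _feature_matrix(config: SyntheticSpectraConfig, wavelengths: np.ndarray,
                    traits: list[str]) -> np.ndarray:
    """(n_traits, n_bands) Gaussian absorption profiles scaled by depth."""
    F = np.zeros((len(traits), wavelengths.size))
    for k, trait in enumerate(traits):
        center, width, depth = config.features[trait]
        F[k] = depth * np.exp(-((wavelengths - center) ** 2) / (2.0 * width**2))
    return F


def simulate_spectra(
    crowns: CrownSet,
    config: SyntheticSpectraConfig | None = None,
    dialect: str = "6nm",
    seed: int = 0,
    landscape: LandscapeRasters | None = None,
    trait_surfaces: dict[str, Raster] | None = None,
    pixel_size: float = 4.0,
    flight_id: str = "F1",
    solar_zenith: float = 30.0,
    region: tuple[float, float, float, float] | None = None,
    min_canopy_height: float = 4.0,
    only_crown_neighborhoods: bool = False,
) -> SpectraCube:
    """Simulate one flight line's reflectance cube over ``region``.

    Pixels whose centre falls in a crown take that tree's traits; other
    pixels take the local trait-surface value when a landscape with TCH
    >= ``min_canopy_height`` is supplied (vegetated matrix between the
    crowns), and a low-NDVI soil spectrum otherwise.  The 12 nm dialect
    is the 6 nm wavelength grid decimated to every second band.
    """
    cfg = config or SyntheticSpectraConfig()
    trait_list = [t for t in cfg.features if t in crowns.traits.columns]
    missing = set(cfg.features) - set(crowns.traits.columns)
    if missing:
        raise ValueError(f"crowns lack traits referenced by absorption features: {sorted(missing)}")
    if dialect == "6nm":
        wavelengths = cfg.wavelengths
    elif dialect == "12nm":
        wavelengths = cfg.wavelengths[::2]
    else:
        raise ValueError(f"dialect must be '6nm' or '12nm', got {dialect!r}")

    rng = np.random.default_rng(seed)
    if region is None:
        if landscape is not None:
            region = landscape.grid.extent
        else:
            bounds = np.array([crowns.polygons[t].bounds for t in crowns.tree_ids])
            m = 3 * pixel_size
            region = (bounds[:, 0].min() - m, bounds[:, 1].min() - m,
                      bounds[:, 2].max() + m, bounds[:, 3].max() + m)
    xmin, ymin, xmax, ymax = region
    if only_crown_neighborhoods:
        # fine-pixel passes covering each crown's window only, as when a
        # survey is subset to the field plots; pixel centres stay on the
        # global pixel lattice so windows never duplicate pixels
        m = 2 * pixel_size
        blocks = []
        for tid in crowns.tree_ids:
            bx0, by0, bx1, by1 = crowns.polygons[tid].bounds
            xs = np.arange(
                xmin + (np.floor((bx0 - m - xmin) / pixel_size) + 0.5) * pixel_size,
                bx1 + m, pixel_size)
            ys = np.arange(
                ymin + (np.floor((by0 - m - ymin) / pixel_size) + 0.5) * pixel_size,
                by1 + m, pixel_size)
            XX, YY = np.meshgrid(xs, ys)
            blocks.append(np.column_stack([XX.ravel(), YY.ravel()]))
        xy = np.unique(np.vstack(blocks), axis=0)
        inside = (xy[:, 0] > xmin) & (xy[:, 0] < xmax) & (xy[:, 1] > ymin) & (xy[:, 1] < ymax)
        xy = xy[inside]
    else:
        xs = np.arange(xmin + pixel_size / 2, xmax, pixel_size)
        ys = np.arange(ymin + pixel_size / 2, ymax, pixel_size)
        XX, YY = np.meshgrid(xs, ys)
        xy = np.column_stack([XX.ravel(), YY.ravel()])
    n = xy.shape[0]

    # crown membership by pixel centre
    tree_of = np.full(n, -1)
    ids = crowns.tree_ids
    from shapely import STRtree, points

    tree_geoms = [crowns.polygons[t] for t in ids]
    strtree = STRtree(tree_geoms)
    pts = points(xy)
    pix_idx, crown_idx = strtree.query(pts, predicate="within")
    tree_of[pix_idx] = crown_idx

    trait_vals = np.zeros((n, len(trait_list)))
    veg = np.zeros(n, dtype=bool)
    in_crown = tree_of >= 0
    veg |= in_crown
    for k, trait in enumerate(trait_list):
        vals = crowns.traits[trait].to_numpy()
        trait_vals[in_crown, k] = vals[tree_of[in_crown]]
    if landscape is not None and trait_surfaces is not None:
        tch = landscape.tch.sample(xy[:, 0], xy[:, 1])
        matrix = (~in_crown) & (tch >= min_canopy_height)
        veg |= matrix
        for k, trait in enumerate(trait_list):
            if trait in trait_surfaces:
                trait_vals[matrix, k] = trait_surfaces[trait].sample(xy[matrix, 0], xy[matrix, 1])

    F = _feature_matrix(cfg, wavelengths, trait_list)
    base_veg = _vegetation_baseline(wavelengths)
    base_soil = _soil_baseline(wavelengths)

    brightness = np.exp(rng.normal(0.0, cfg.brightness_sd, size=n))
    crown_offsets = rng.normal(0.0, cfg.crown_effect_sd, size=len(ids))
    noise = rng.normal(0.0, cfg.pixel_noise_sd, size=(n, wavelengths.size)) \
        if cfg.pixel_noise_sd > 0 else 0.0

    refl = np.tile(base_soil, (n, 1))
    refl[veg] = brightness[veg, None] * base_veg[None, :] - trait_vals[veg] @ F
    refl[in_crown] += crown_offsets[tree_of[in_crown], None]
    refl = np.clip(refl + noise, 0.0, 1.0)

    return SpectraCube(
        wavelengths=wavelengths,
        reflectance=refl,
        xy=xy,
        pixel_size=pixel_size,
        flight_id=flight_id,
        solar_zenith=solar_zenith,
        dialect=dialect,
        history=("simulated",),
    )
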