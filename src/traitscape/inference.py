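"""Bootstrapped spatial-autoregressive inference on trait rasters.

Trait maps are spatially autocorrelated, so effects of disturbance
history, elevation and canopy height are estimated with a simultaneous
autoregressive (SAR) *error* model,

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I),

where W is a row-standardized distance-band neighbourhood (first-order
extent chosen from semivariograms of OLS residuals; 2 km by default).
The fit maximizes the profile likelihood in lambda, using the eigenvalue
form of the log-determinant of (I - lambda W).  Uncertainty comes from a
bootstrap: the model is refitted on many random samples of cells and
95% intervals are taken as the 2.5th/97.5th percentiles of the
estimates; a coefficient is called significant when that interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import curve_fit, minimize_scalar
from scipy.spatial import cKDTree

from .grids import Raster
from .plsr import TraitRaster
from .synthetic import LandscapeRasters
from .traitmodel import TERMS, TraitModel, predict_at

__all__ = [
    "SpatialWeights",
    "Semivariogram",
    "SARFit",
    "BootstrapSummary",
    "build_neighborhood",
    "ols_residuals",
    "ols_residual_semivariogram",
    "fit_sar_error",
    "bootstrap_sar",
    "predict_at",
    "percent_change",
    "classify_colimitation",
]


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Distance-band neighbourhood over cell centroids."""

    W: sparse.csr_matrix  # weights actually used in the model
    binary: sparse.csr_matrix  # symmetric 0/1 adjacency
    coords: np.ndarray
    band: float
    style: str  # "row" | "binary"
    isolates: np.ndarray  # indices of cells with no neighbour

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_neighborhood(coords: np.ndarray, band: float = 2000.0, style: str = "row") -> SpatialWeights:
    """Neighbours are cells whose centroids lie within ``band`` metres.

    Weights are row-standardized by default (``style="binary"`` keeps
    0/1).  Cells with no neighbour are permitted but flagged as
    isolates; their weight rows are zero.
    """
    if style not in ("row", "binary"):
        raise ValueError(f"style must be 'row' or 'binary', got {style!r}")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(band, output_type="ndarray")
    if pairs.size:
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        B = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    else:
        B = sparse.csr_matrix((n, n))
    deg = np.asarray(B.sum(axis=1)).ravel()
    isolates = np.nonzero(deg == 0)[0]
    if style == "row":
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        W = sparse.diags(inv) @ B
    else:
        W = B.copy()
    return SpatialWeights(W=W.tocsr(), binary=B.tocsr(), coords=coords, band=band,
                          style=style, isolates=isolates)


# ---------------------------------------------------------------------------
# semivariograms on OLS residuals


@dataclass
class Semivariogram:
    """Directional Matheron semivariogram with fitted range per direction."""

    directions: np.ndarray  # degrees
    lags: np.ndarray  # bin centres, m
    semivariance: np.ndarray  # (n_directions, n_lags); NaN where no pairs
    counts: np.ndarray
    range_estimates: np.ndarray  # practical range per direction, m (NaN if unfit)


def ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of the OLS fit; rejects rank-deficient designs."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear columns)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _exp_model(h: np.ndarray, c0: float, c1: float, r: float) -> np.ndarray:
    return c0 + c1 * (1.0 - np.exp(-3.0 * h / r))


def ols_residual_semivariogram(
    values: np.ndarray,
    coords: np.ndarray,
    X: np.ndarray | None = None,
    max_range: float = 4000.0,
    n_lags: int = 10,
    directions: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    angle_tol: float = 22.5,
) -> Semivariogram:
    """Anisotropic semivariogram of OLS residuals up to ``max_range``.

    ``values`` are the response at ``coords``; when a design matrix is
    given the classical (Matheron) estimator runs on its OLS residuals,
    otherwise on the centred values.  The practical range per direction
    comes from an exponential-model fit (NaN when the fit fails).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 100:
        raise ValueError("need at least 100 cells with data for a semivariogram")
    resid = ols_residuals(values, X) if X is not None else np.asarray(values, float) - np.mean(values)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_range, output_type="ndarray")
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    dist = np.hypot(d[:, 0], d[:, 1])
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    sq = 0.5 * (resid[pairs[:, 0]] - resid[pairs[:, 1]]) ** 2

    edges = np.linspace(0.0, max_range, n_lags + 1)
    lag_bin = np.clip(np.digitize(dist, edges) - 1, 0, n_lags - 1)
    lags = 0.5 * (edges[:-1] + edges[1:])

    dirs = np.asarray(directions, dtype=float)
    gamma = np.full((dirs.size, n_lags), np.nan)
    counts = np.zeros((dirs.size, n_lags), dtype=int)
    ranges = np.full(dirs.size, np.nan)
    for i, d0 in enumerate(dirs):
        diff = np.abs((ang - d0 + 90.0) % 180.0 - 90.0)
        in_dir = diff <= angle_tol
        if not in_dir.any():
            continue
        s = np.bincount(lag_bin[in_dir], weights=sq[in_dir], minlength=n_lags)
        c = np.bincount(lag_bin[in_dir], minlength=n_lags)
        counts[i] = c
        with np.errstate(invalid="ignore"):
            gamma[i] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        ok = c > 0
        if ok.sum() >= 4 and np.nanmax(gamma[i]) > 0:
            sill = float(np.nanmax(gamma[i]))
            try:
                popt, _ = curve_fit(
                    _exp_model, lags[ok], gamma[i][ok],
                    p0=(gamma[i][ok][0], sill, max_range / 4),
                    bounds=([0, 0, 1e-6], [np.inf, np.inf, 10 * max_range]),
                    maxfev=5000,
                )
                ranges[i] = popt[2]
            except RuntimeError:
                pass
    return Semivariogram(directions=dirs, lags=lags, semivariance=gamma,
                         counts=counts, range_estimates=ranges)


# ---------------------------------------------------------------------------
# SAR error-model maximum likelihood


@dataclass
class SARFit:
    terms: tuple[str, ...]
    beta: np.ndarray
    lam: float
    sigma2: float
    loglik: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.terms))


def _sar_eigenvalues(weights: SpatialWeights) -> np.ndarray:
    """Real eigenvalues of W for the log-determinant of (I - lambda W).

    A row-standardized W from a symmetric binary adjacency is similar to
    the symmetric matrix D^-1/2 B D^-1/2, so its spectrum is real.
    Isolate rows contribute zero eigenvalues.
    """
    B = weights.binary
    deg = np.asarray(B.sum(axis=1)).ravel()
    if weights.style == "row":
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1)), 0.0)
        S = sparse.diags(dinv) @ B @ sparse.diags(dinv)
        return np.linalg.eigvalsh(S.toarray())
    return np.linalg.eigvalsh(B.toarray())


def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
    terms: tuple[str, ...] = TERMS,
    lam: float | None = None,
) -> SARFit:
    """Maximum-likelihood SAR error-model fit.

    Passing ``lam`` fixes the autoregressive parameter (``lam=0``
    reduces exactly to OLS).  Otherwise the profile log-likelihood

        l(lambda) = log|I - lambda W| - (n/2) log(SSR(lambda)/n)

    is maximized over the stable interval, where SSR(lambda) is the
    residual sum of squares of the spatially filtered regression
    (I - lambda W)y on (I - lambda W)X.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more cells ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is singular (collinear columns)")
    W = weights.W
    Wy = W @ y
    WX = W @ X

    def beta_ssr(lam_: float) -> tuple[np.ndarray, float]:
        Ay = y - lam_ * Wy
        AX = X - lam_ * WX
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        r = Ay - AX @ beta
        return beta, float(r @ r)

    if lam is not None:
        beta, ssr = beta_ssr(lam)
        sigma2 = ssr / n
        eig = _sar_eigenvalues(weights)
        logdet = float(np.sum(np.log(np.abs(1.0 - lam * eig)))) if lam else 0.0
        ll = logdet - 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return SARFit(tuple(terms), beta, float(lam), sigma2, ll)

    eig = _sar_eigenvalues(weights)
    lo = 1.0 / eig.min() + 1e-6 if eig.min() < 0 else -0.999
    hi = 1.0 / eig.max() - 1e-6 if eig.max() > 0 else 0.999

    def negll(lam_: float) -> float:
        _, ssr = beta_ssr(lam_)
        logdet = float(np.sum(np.log(np.abs(1.0 - lam_ * eig))))
        return 0.5 * len(y) * np.log(ssr / len(y)) - logdet

    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    lam_hat = float(res.x)
    beta, ssr = beta_ssr(lam_hat)
    sigma2 = ssr / n
    logdet = float(np.sum(np.log(np.abs(1.0 - lam_hat * eig))))
    ll = logdet - 0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return SARFit(tuple(terms), beta, lam_hat, sigma2, ll)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapSummary:
    """Bootstrap SAR estimates: per-term mean, percentile CI, significance."""

    trait: str
    terms: tuple[str, ...]
    estimates: np.ndarray  # (n_boot, n_terms)
    lambdas: np.ndarray
    n_boot: int
    sample_size: int
    seed: int
    n_failures: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.estimates.mean(axis=0)

    @property
    def ci(self) -> np.ndarray:
        """(n_terms, 2): 2.5th and 97.5th percentiles."""
        return np.percentile(self.estimates, [2.5, 97.5], axis=0).T

    @property
    def significant(self) -> np.ndarray:
        ci = self.ci
        return (ci[:, 0] > 0) | (ci[:, 1] < 0)

    def table(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "mean": self.mean,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "significant": self.significant,
            }
        ).set_index("term")


def _design_from_rasters(
    trait_raster: TraitRaster | Raster,
    covariates: LandscapeRasters,
    model: TraitModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y, X, coords) over cells where trait and covariates all have data,
    in canonical (row-major) cell order."""
    r = trait_raster.raster if isinstance(trait_raster, TraitRaster) else trait_raster
    if r.grid != covariates.grid:
        raise ValueError("trait raster and covariates must share one grid")
    ok = r.mask & covariates.elevation.mask & covariates.tch.mask & covariates.disturbance.mask
    y = r.values[ok]
    X = model.design_matrix(
        covariates.disturbance.values[ok],
        covariates.elevation.values[ok],
        covariates.tch.values[ok],
    )
    xs, ys = r.grid.cell_centers()
    coords = np.column_stack([xs[ok], ys[ok]])
    return y, X, coords


def bootstrap_sar(
    trait_raster: TraitRaster | Raster,
    covariates: LandscapeRasters,
    n_boot: int = 1000,
    sample_size: int = 1000,
    seed: int = 0,
    band: float = 2000.0,
    replace: bool = False,
    model: TraitModel | None = None,
    trait: str = "trait",
    max_failures: int = 50,
    replicate_seeds: list[int] | None = None,
) -> BootstrapSummary:
    """Fit the SAR error model on ``n_boot`` random cell samples.

    Each replicate draws ``sample_size`` cells (without replacement by
    default — subsampling; with replacement via ``replace=True``),
    rebuilds the distance-band neighbourhood among the sampled cells and
    fits by ML.  A replicate whose fit fails is logged and redrawn.
    Deterministic given ``seed`` and independent of input cell ordering
    (cells are canonically ordered before sampling).
    """
    mdl = model or TraitModel({t: 0.0 for t in TERMS})
    y, X, coords = _design_from_rasters(trait_raster, covariates, mdl)
    n = y.size
    if n < sample_size:
        raise ValueError(f"raster has {n} usable cells; need at least sample_size={sample_size}")
    order = np.lexsort((coords[:, 0], coords[:, 1]))
    y, X, coords = y[order], X[order], coords[order]

    if replicate_seeds is not None and len(replicate_seeds) != n_boot:
        raise ValueError("replicate_seeds must have one entry per bootstrap replicate")
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_boot, X.shape[1]))
    lambdas = np.empty(n_boot)
    failures = 0
    b = 0
    while b < n_boot:
        draw_rng = rng if replicate_seeds is None else np.random.default_rng(replicate_seeds[b])
        idx = draw_rng.choice(n, size=sample_size, replace=replace)
        try:
            w = build_neighborhood(coords[idx], band=band)
            fit = fit_sar_error(y[idx], X[idx], w)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"bootstrap abandoned after {failures} failed replicate fits"
                )
            continue
        estimates[b] = fit.beta
        lambdas[b] = fit.lam
        b += 1
    return BootstrapSummary(
        trait=trait,
        terms=TERMS,
        estimates=estimates,
        lambdas=lambdas,
        n_boot=n_boot,
        sample_size=sample_size,
        seed=seed,
        n_failures=failures,
    )


# ---------------------------------------------------------------------------
# worked-example calculators


def percent_change(reference: float, comparison: float) -> float:
    """Percent reduction from ``reference`` to ``comparison``:
    100 (reference - comparison) / reference."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return 100.0 * (reference - comparison) / reference


def classify_colimitation(np_ratio: float) -> str:
    """Nutrient-limitation class from the foliar N:P mass ratio.

    Ratios in the closed band [14, 16] indicate N and P co-limitation;
    below it nitrogen limits, above it phosphorus limits.
    """
    if not np.isfinite(np_ratio) or np_ratio <= 0:
        raise ValueError(f"N:P ratio must be positive, got {np_ratio}")
    if np_ratio < 14.0:
        return "N-limited"
    if np_ratio <= 16.0:
        return "co-limiting"
    return "P-limited"
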