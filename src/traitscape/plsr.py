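"""PLSR trait calibration, grouped cross-validation and trait mapping.

Partial least squares regression (NIPALS, via scikit-learn) predicts a
foliar trait from processed pixel spectra.  Model skill is assessed two
ways: leave-one-pixel-out (LOPO), the conventional choice, and
leave-one-tree-out (LOTO), which holds out every pixel of a crown
together and is the honest metric when within-crown spectral variation
is shared — LOPO leaks crown-level structure into training and inflates
skill.  Component count is chosen by the one-standard-error rule.
Skill metrics are R^2 of prediction (percent), RMSE in trait units and
RMSE as a percentage of the trait mean.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .cube import SpectraCube
from .grids import Grid, Raster
from .preprocess import CalibrationTable, FilterConfig, compute_ndvi

__all__ = [
    "PLSRModel",
    "CVResult",
    "TraitRaster",
    "fit_plsr",
    "cross_validate",
    "select_components",
    "rmse",
    "pct_rmse",
    "r2",
    "predict_map",
    "mosaic",
    "LOG_TRAITS",
]

#: Traits fitted on a log-transformed response (back-transformed at prediction).
LOG_TRAITS = ("N_pct", "P_pct", "SLA_mm2_mg")


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length, non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pct_rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """RMSE as a percentage of mean(y)."""
    ybar = float(np.mean(y))
    if ybar == 0:
        raise ValueError("%RMSE undefined: mean of the observations is zero")
    return 100.0 * rmse(y, yhat) / ybar


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """R^2 of prediction in percent: (1 - SSE/SST) x 100; negative when
    predictions do worse than the mean."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length, non-empty vectors")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant observations")
    sse = float(np.sum((y - yhat) ** 2))
    return (1.0 - sse / sst) * 100.0


def _transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive trait values")
        return np.log(y)
    raise ValueError(f"unknown response transform {transform!r}")


def _back_transform(y: np.ndarray, transform: str) -> np.ndarray:
    return np.exp(y) if transform == "log" else y


def _pipeline_hash(history: list[str] | tuple[str, ...]) -> str:
    return hashlib.sha256("|".join(history).encode()).hexdigest()[:16]


@dataclass
class PLSRModel:
    """Fitted PLSR trait model on a fixed processed wavelength grid."""

    trait: str
    n_components: int
    transform: str
    wavelengths: np.ndarray
    coef: np.ndarray  # regression vector on centred spectra (transformed scale)
    x_mean: np.ndarray
    y_mean: float  # transformed scale
    n_pixels: int
    n_trees: int
    pipeline_hash: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"spectrum has {X.shape[1]} bands; model was trained on {self.wavelengths.size}"
            )
        z = (X - self.x_mean) @ self.coef + self.y_mean
        return _back_transform(z, self.transform)


def _coef_for_k(pls: PLSRegression, k: int) -> np.ndarray:
    """Regression vector using only the first k latent components."""
    if k == 0:
        return np.zeros(pls.x_rotations_.shape[0])
    return (pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T).ravel()


def fit_plsr(
    table: CalibrationTable,
    trait: str,
    n_components: int,
    transform: str = "identity",
) -> PLSRModel:
    """Fit PLSR of one trait on the table's processed spectra.

    ``n_components = 0`` yields the null (training-mean) model.  The fit
    is deterministic given row order.  Repeat observations of a tree
    from different flights enter as separate rows; they are never
    pre-averaged.
    """
    X, y, groups = table.rows_for_trait(trait)
    if X.shape[0] == 0:
        raise ValueError("calibration table has no rows; refusing to fit")
    yt = _transform(y, transform)
    if np.ptp(yt) == 0:
        raise ValueError(f"trait {trait!r} is constant; PLSR fit rejected")
    if n_components < 0 or n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"n_components must be in [0, min(n_rows - 1, n_bands)] = "
            f"[0, {min(X.shape[0] - 1, X.shape[1])}], got {n_components}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(yt.mean())
    if n_components == 0:
        coef = np.zeros(X.shape[1])
    else:
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, yt)
        coef = _coef_for_k(pls, n_components)
    return PLSRModel(
        trait=trait,
        n_components=n_components,
        transform=transform,
        wavelengths=table.wavelengths.copy(),
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        n_pixels=X.shape[0],
        n_trees=len(np.unique(groups)),
        pipeline_hash=_pipeline_hash(table.provenance.get("pipeline", [])),
    )


def select_components(
    cv_errors: np.ndarray,
    se_at_best: float,
    k_values: np.ndarray | None = None,
) -> int:
    """One-standard-error rule: the smallest component count whose CV error
    is within one SE of the best model's error."""
    cv_errors = np.asarray(cv_errors, dtype=float)
    if cv_errors.size == 0:
        raise ValueError("empty CV error curve")
    k_values = np.arange(cv_errors.size) if k_values is None else np.asarray(k_values)
    best = int(np.argmin(cv_errors))
    threshold = cv_errors[best] + max(se_at_best, 0.0)
    eligible = np.nonzero(cv_errors <= threshold)[0]
    return int(k_values[eligible[0]])


@dataclass
class CVResult:
    """Grouped cross-validation outcome for one trait and scheme."""

    scheme: str  # "LOPO" | "LOTO"
    trait: str
    transform: str
    k_values: np.ndarray
    cv_curve: np.ndarray  # CV RMSE per component count, original trait scale
    fold_errors: dict[int, np.ndarray]  # k -> per-fold RMSE
    n_components: int
    y: np.ndarray
    yhat: np.ndarray  # CV predictions at the chosen component count
    groups: np.ndarray
    r2: float | None
    rmse: float | None
    pct_rmse: float | None

    @property
    def n_folds(self) -> int:
        return len(np.unique(self.groups))


def cross_validate(
    table: CalibrationTable,
    trait: str,
    scheme: str = "LOTO",
    max_components: int = 10,
    transform: str | None = None,
    min_components: int = 0,
) -> CVResult:
    """Leave-one-pixel-out or leave-one-tree-out cross-validation.

    LOPO folds are single rows; LOTO folds are the distinct tree_ids, so
    a held-out tree's pixels never inform its own prediction.  The CV
    error curve (RMSE on the original trait scale) is recorded for every
    component count up to ``max_components``; the reported metrics use
    the component count chosen by the one-SE rule.  A 0-component choice
    means the spectra carry no usable signal: the model collapses to the
    training mean and R^2 / %RMSE are suppressed (None).
    """
    if scheme not in ("LOPO", "LOTO"):
        raise ValueError(f"scheme must be 'LOPO' or 'LOTO', got {scheme!r}")
    if transform is None:
        transform = "log" if trait in LOG_TRAITS else "identity"
    X, y, tree_ids = table.rows_for_trait(trait)
    n = X.shape[0]
    if n == 0:
        raise ValueError("calibration table has no rows; refusing to cross-validate")
    fold_keys = np.arange(n) if scheme == "LOPO" else tree_ids
    unique_folds = np.unique(fold_keys)
    if scheme == "LOTO" and unique_folds.size < 2:
        raise ValueError("LOTO requires more than one tree")
    if unique_folds.size < 3:
        raise ValueError(f"need at least 3 folds, got {unique_folds.size}")

    yt = _transform(y, transform)
    max_k = min(max_components, n - int(np.max(np.bincount(
        np.searchsorted(unique_folds, fold_keys)))) - 1, X.shape[1])
    k_values = np.arange(min_components, max_k + 1)

    preds = np.empty((k_values.size, n))
    for fold in unique_folds:
        test = fold_keys == fold
        train = ~test
        Xtr, ytr = X[train], yt[train]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        if k_values[-1] > 0:
            pls = PLSRegression(n_components=int(k_values[-1]), scale=False)
            pls.fit(Xtr, ytr)
        for ki, k in enumerate(k_values):
            if k == 0:
                z = np.full(int(test.sum()), y_mean)
            else:
                z = (X[test] - x_mean) @ _coef_for_k(pls, int(k)) + y_mean
            preds[ki, test] = z

    preds = _back_transform(preds, transform)
    cv_curve = np.array([rmse(y, preds[ki]) for ki in range(k_values.size)])
    fold_errors = {}
    fold_index = [fold_keys == f for f in unique_folds]
    for ki, k in enumerate(k_values):
        fold_errors[int(k)] = np.array([rmse(y[m], preds[ki][m]) for m in fold_index])
    best_ki = int(np.argmin(cv_curve))
    fe = fold_errors[int(k_values[best_ki])]
    se_at_best = float(fe.std(ddof=1) / np.sqrt(fe.size)) if fe.size > 1 else 0.0
    chosen = select_components(cv_curve, se_at_best, k_values)
    yhat = preds[int(np.nonzero(k_values == chosen)[0][0])]

    suppress = chosen == 0
    return CVResult(
        scheme=scheme,
        trait=trait,
        transform=transform,
        k_values=k_values,
        cv_curve=cv_curve,
        fold_errors=fold_errors,
        n_components=chosen,
        y=y,
        yhat=yhat,
        groups=np.asarray(fold_keys),
        r2=None if suppress else r2(y, yhat),
        rmse=None if suppress else rmse(y, yhat),
        pct_rmse=None if suppress else pct_rmse(y, yhat),
    )


@dataclass
class TraitRaster:
    """Gridded trait predictions with provenance."""

    raster: Raster
    trait: str
    n_contributions: np.ndarray
    model_ref: str = ""

    def __post_init__(self) -> None:
        if self.n_contributions.shape != self.raster.grid.shape:
            raise ValueError("n_contributions must match the raster grid")


def predict_map(
    model: PLSRModel,
    cube: SpectraCube,
    chm: Raster,
    grid: Grid | None = None,
    filters: FilterConfig | None = None,
) -> TraitRaster:
    """Predict a trait for every vegetation pixel and average to 1-ha cells.

    Vegetation pixels are those at canopy height >= ``min_height`` with
    NDVI >= ``min_ndvi``; cells containing none are missing, not zero.
    The cube must be on the model's wavelength grid and processed by the
    same pipeline (checked via the recorded provenance hash).
    """
    cfg = filters or FilterConfig()
    if cube.wavelengths.size != model.wavelengths.size or not np.allclose(
        cube.wavelengths, model.wavelengths
    ):
        raise ValueError("cube wavelength grid does not match the model's training grid")
    if model.pipeline_hash and _pipeline_hash(cube.history) != model.pipeline_hash:
        raise ValueError(
            "cube processing history does not match the model's training pipeline: "
            f"{list(cube.history)}"
        )
    if grid is None:
        x0, y0 = chm.grid.origin
        xmin, ymin, xmax, ymax = chm.grid.extent
        grid = Grid(
            shape=(int(round((ymax - ymin) / 100.0)), int(round((xmax - xmin) / 100.0))),
            cell_size=100.0,
            origin=(x0, y0),
        )

    heights = chm.sample(cube.xy[:, 0], cube.xy[:, 1])
    ndvi = compute_ndvi(cube.reflectance, cube.wavelengths, cfg.red_nm, cfg.nir_nm)
    veg = (heights >= cfg.min_height) & (np.nan_to_num(ndvi, nan=-np.inf) >= cfg.min_ndvi)

    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape, dtype=int)
    if veg.any():
        pred = model.predict(cube.reflectance[veg])
        row, col = grid.index_of(cube.xy[veg, 0], cube.xy[veg, 1])
        flat = row * grid.ncols + col
        sums = np.bincount(flat, weights=pred, minlength=grid.nrows * grid.ncols)
        nums = np.bincount(flat, minlength=grid.nrows * grid.ncols)
        with np.errstate(invalid="ignore"):
            cellmean = np.where(nums > 0, sums / np.maximum(nums, 1), np.nan)
        values = cellmean.reshape(grid.shape)
        counts = nums.reshape(grid.shape).astype(int)
    return TraitRaster(
        raster=Raster(grid, values, model.trait),
        trait=model.trait,
        n_contributions=(counts > 0).astype(int),
        model_ref=f"plsr:{model.trait}:{model.n_components}:{model.pipeline_hash}",
    )


def mosaic(rasters: list[TraitRaster]) -> TraitRaster:
    """Cellwise unweighted mean across flight-line trait rasters."""
    if not rasters:
        raise ValueError("no rasters to mosaic")
    g0 = rasters[0].raster.grid
    for tr in rasters[1:]:
        if tr.raster.grid != g0:
            raise ValueError("mosaic requires rasters on one shared grid")
        if tr.trait != rasters[0].trait:
            raise ValueError("mosaic mixes different traits")
    stack = np.stack([tr.raster.values for tr in rasters])
    has = np.isfinite(stack)
    n = has.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(has, stack, 0.0), axis=0) / np.maximum(n, 1), np.nan)
    return TraitRaster(
        raster=Raster(g0, mean, rasters[0].trait),
        trait=rasters[0].trait,
        n_contributions=n.astype(int),
        model_ref=";".join(sorted({tr.model_ref for tr in rasters})),
    )
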