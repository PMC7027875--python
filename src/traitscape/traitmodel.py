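"""Linear trait–landscape model shared by the generator and the inference code.

Canopy foliar traits are modelled as linear functions of disturbance
history (old-growth vs. logged), elevation and top-of-canopy height (TCH),
including all interactions:

    trait = b0 + b1 L + b2 z_e + b3 z_t + b4 L z_e + b5 L z_t + b6 z_e z_t + b7 L z_e z_t

where ``L`` is the logged indicator and the continuous covariates are
standardized against a reference stand of 30 m tall forest at 200 m
a.s.l.: ``z_e = (elevation - 200)/155`` and ``z_t = (tch - 30)/7.3``.
Coefficients for elevation and TCH are therefore per standard deviation
of the predictor, and the intercept is the expected trait value of the
reference stand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Design-matrix terms, in column order.
TERMS: tuple[str, ...] = (
    "reference",
    "logged",
    "elevation",
    "tch",
    "logged_x_elevation",
    "logged_x_tch",
    "elevation_x_tch",
    "logged_x_elevation_x_tch",
)

#: Trait columns used throughout the package.
TRAIT_NAMES: tuple[str, ...] = ("N_pct", "P_pct", "NP_ratio", "SLA_mm2_mg")

#: Centering constants (reference stand) and predictor standard deviations.
TCH_CENTER = 30.0  # m
ELEV_CENTER = 200.0  # m a.s.l.
TCH_SCALE = 7.3  # m
ELEV_SCALE = 155.0  # m

#: Decimal places used when reporting each trait.
REPORT_DECIMALS: dict[str, int] = {"N_pct": 2, "P_pct": 3, "NP_ratio": 1, "SLA_mm2_mg": 1}


@dataclass(frozen=True)
class TraitModel:
    """Coefficients (one per term of :data:`TERMS`) with their standardization."""

    coefficients: Mapping[str, float]
    tch_center: float = TCH_CENTER
    elev_center: float = ELEV_CENTER
    tch_scale: float = TCH_SCALE
    elev_scale: float = ELEV_SCALE

    def __post_init__(self) -> None:
        missing = [t for t in TERMS if t not in self.coefficients]
        if missing:
            raise ValueError(f"coefficient table is missing terms: {missing}")
        if self.tch_scale <= 0 or self.elev_scale <= 0:
            raise ValueError("standardization scales must be strictly positive")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in TERMS], dtype=float)

    def standardize(self, elevation: np.ndarray, tch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z_e = (np.asarray(elevation, dtype=float) - self.elev_center) / self.elev_scale
        z_t = (np.asarray(tch, dtype=float) - self.tch_center) / self.tch_scale
        return z_e, z_t

    def design_matrix(
        self, logged: np.ndarray, elevation: np.ndarray, tch: np.ndarray
    ) -> np.ndarray:
        """n x 8 design matrix in :data:`TERMS` order from raw covariates."""
        L = np.asarray(logged, dtype=float)
        if not np.isin(L, (0.0, 1.0)).all():
            raise ValueError("logged indicator must be two-valued (0/1)")
        z_e, z_t = self.standardize(elevation, tch)
        one = np.ones_like(L)
        return np.column_stack(
            [one, L, z_e, z_t, L * z_e, L * z_t, z_e * z_t, L * z_e * z_t]
        )

    def linear_predictor(
        self, logged: np.ndarray, elevation: np.ndarray, tch: np.ndarray
    ) -> np.ndarray:
        X = self.design_matrix(np.atleast_1d(logged), np.atleast_1d(elevation), np.atleast_1d(tch))
        return X @ self.beta


def predict_at(
    model: TraitModel | Mapping[str, float],
    disturbance: str,
    tch: float,
    elevation: float,
) -> float:
    """Expected trait value at a stand condition from a coefficient table.

    ``disturbance`` is ``"old-growth"`` or ``"logged"``; ``tch`` and
    ``elevation`` are in metres.  Rounding is left to the caller: the
    plain linear predictor is returned.
    """
    if not isinstance(model, TraitModel):
        model = TraitModel(dict(model))
    if disturbance not in ("old-growth", "logged"):
        raise ValueError(f"disturbance must be 'old-growth' or 'logged', got {disturbance!r}")
    logged = 1.0 if disturbance == "logged" else 0.0
    return float(model.linear_predictor(logged, elevation, tch)[0])


#: Published bootstrapped SAR coefficient estimates for a logged-forest
#: landscape in Sabah, Borneo (mean estimates; reference stand 30 m tall
#: old-growth forest at 200 m a.s.l.).  These ship as the default
#: generative truth so parameter-recovery tests are self-describing.
REFERENCE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "N_pct": {
        "reference": 2.34,
        "logged": -0.52,
        "elevation": -0.11,
        "tch": -0.03,
        "logged_x_elevation": 0.08,
        "logged_x_tch": -0.06,
        "elevation_x_tch": 0.02,
        "logged_x_elevation_x_tch": -0.01,
    },
    "P_pct": {
        "reference": 0.178,
        "logged": -0.063,
        "elevation": -0.016,
        "tch": 0.000,
        "logged_x_elevation": 0.010,
        "logged_x_tch": -0.010,
        "elevation_x_tch": 0.001,
        "logged_x_elevation_x_tch": 0.000,
    },
    "NP_ratio": {
        "reference": 15.1,
        "logged": 2.14,
        "elevation": 0.92,
        "tch": -1.80,
        "logged_x_elevation": 0.33,
        "logged_x_tch": 0.36,
        "elevation_x_tch": 0.05,
        "logged_x_elevation_x_tch": -0.06,
    },
    "SLA_mm2_mg": {
        "reference": 10.8,
        "logged": -0.85,
        "elevation": -0.14,
        "tch": 0.12,
        "logged_x_elevation": -0.00,
        "logged_x_tch": -0.32,
        "elevation_x_tch": -0.02,
        "logged_x_elevation_x_tch": 0.11,
    },
}


def reference_model(trait: str) -> TraitModel:
    """Default :class:`TraitModel` for one of :data:`TRAIT_NAMES`."""
    if trait not in REFERENCE_COEFFICIENTS:
        raise KeyError(f"no reference coefficients for trait {trait!r}")
    return TraitModel(REFERENCE_COEFFICIENTS[trait])
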