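"""In-memory container for georeferenced reflectance spectra.

A :class:`SpectraCube` holds one flight line's worth of pixel spectra as a
dense (n_pixels, n_bands) array plus per-band wavelength centres.  Pixels
are square, identified by their centre coordinates in the same planar
metric frame as the rasters.  The ``history`` tuple records the
post-processing steps applied, so downstream model fitting can refuse
spectra that were not processed the same way as its training data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

DIALECTS = ("6nm", "12nm")


@dataclass
class SpectraCube:
    wavelengths: np.ndarray  # nm, strictly ascending
    reflectance: np.ndarray  # (n_pixels, n_bands), values in [0, 1]
    xy: np.ndarray  # (n_pixels, 2) pixel-centre coordinates, m
    pixel_size: float  # m
    flight_id: str = "F0"
    solar_zenith: float = 30.0  # degrees, scene constant
    dialect: str = "6nm"
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.reflectance.ndim != 2 or self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.xy.shape != (self.reflectance.shape[0], 2):
            raise ValueError("xy must be (n_pixels, 2)")
        if not np.isfinite(self.reflectance).all():
            raise ValueError("reflectance must be finite")
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}, got {self.dialect!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_pixels(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def with_bands(self, wavelengths: np.ndarray, reflectance: np.ndarray, step: str,
                   dialect: str | None = None) -> "SpectraCube":
        """Copy with a new spectral axis and ``step`` appended to the history."""
        return replace(
            self,
            wavelengths=np.asarray(wavelengths, dtype=float),
            reflectance=np.asarray(reflectance, dtype=float),
            dialect=self.dialect if dialect is None else dialect,
            history=self.history + (step,),
        )

    def subset(self, index: np.ndarray) -> "SpectraCube":
        """Copy restricted to the pixels selected by ``index``."""
        return replace(self, reflectance=self.reflectance[index], xy=self.xy[index])
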