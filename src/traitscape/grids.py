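"""Planar metric grids and single-band rasters.

All geographic handling in this package is planar: coordinates are metres
in an arbitrary projected frame, cell centres carry the values, and the
grid origin sits at the lower-left corner of the lower-left cell.  Row 0
of the value array is the *bottom* row, so ``values[row, col]`` sits at
``(x0 + (col + 0.5) h, y0 + (row + 0.5) h)`` for cell size ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Regular square-celled grid: ``shape`` is (nrows, ncols)."""

    shape: tuple[int, int]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        nrows, ncols = self.shape
        if nrows < 1 or ncols < 1:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of x and y centre coordinates."""
        x0, y0 = self.origin
        h = self.cell_size
        xs = x0 + (np.arange(self.ncols) + 0.5) * h
        ys = y0 + (np.arange(self.nrows) + 0.5) * h
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (clipped to the grid)."""
        x0, y0 = self.origin
        col = np.clip(((np.asarray(x) - x0) // self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((np.asarray(y) - y0) // self.cell_size).astype(int), 0, self.nrows - 1)
        return row, col


@dataclass
class Raster:
    """Single-band raster; missing cells are NaN."""

    grid: Grid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup at point coordinates (metres)."""
        row, col = self.grid.index_of(x, y)
        return self.values[row, col]

    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "Raster":
        return Raster(
            self.grid,
            self.values.copy() if values is None else np.asarray(values, dtype=float),
            self.name if name is None else name,
        )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of cells holding data."""
        return np.isfinite(self.values)
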