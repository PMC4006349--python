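"""Regular-grid containers for images and implicit (level-set) functions.

Fields live on a uniform cell-centered Cartesian grid in 2-D or 3-D with
per-axis physical spacing.  Array axis order is (row, col[, slice]) and
indices are 0-based; physical coordinates are ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "ScalarField", "LevelSetField"]

MIN_EXTENT = 8


@dataclass(frozen=True)
class Grid:
    """Spatial domain: integer extents plus physical cell spacing per axis.

    Parameters
    ----------
    shape : tuple of int
        Cell counts per axis; 2 or 3 axes, each >= 8.
    spacing : tuple of float
        Physical length of one cell per axis (mm); all > 0.  Default 1.0.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...] = ()

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2-D or 3-D, got shape {shape}")
        if any(s < MIN_EXTENT for s in shape):
            raise ValueError(f"all extents must be >= {MIN_EXTENT}, got {shape}")
        spacing = self.spacing or (1.0,) * len(shape)
        spacing = tuple(float(h) for h in spacing)
        if len(spacing) != len(shape):
            raise ValueError("spacing must have one entry per axis")
        if any(h <= 0 for h in spacing):
            raise ValueError(f"spacings must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def h_min(self) -> float:
        return min(self.spacing)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def coordinate_arrays(self) -> list[np.ndarray]:
        """Physical coordinate of every cell center, one array per axis."""
        axes = [np.arange(n) * h for n, h in zip(self.shape, self.spacing)]
        return list(np.meshgrid(*axes, indexing="ij"))

    def contains_index(self, idx) -> bool:
        return len(idx) == self.ndim and all(
            0 <= int(i) < n for i, n in zip(idx, self.shape)
        )


@dataclass
class ScalarField:
    """A real-valued quantity sampled at every cell of a :class:`Grid`."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.grid)

    def integral(self) -> float:
        """Cell-sum approximation of the domain integral."""
        return float(self.values.sum() * self.grid.cell_volume)


@dataclass
class LevelSetField:
    """Implicit region representation phi (interior positive).

    ``eps`` is the narrowband half-width in grid units (multiples of the
    smallest spacing); the regularized Heaviside/delta act on phi values
    using the physical half-width ``eps_phys``.
    """

    values: np.ndarray
    grid: Grid
    eps: float = 1.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("level-set field contains non-finite values")
        if self.eps <= 0:
            raise ValueError(f"narrowband half-width eps must be > 0, got {self.eps}")

    @property
    def eps_phys(self) -> float:
        return self.eps * self.grid.h_min

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.values.copy(), self.grid, self.eps)

    def with_values(self, values: np.ndarray) -> "LevelSetField":
        return LevelSetField(values, self.grid, self.eps)

    def interior_mask(self) -> np.ndarray:
        return self.values > 0

    def band_mask(self) -> np.ndarray:
        return np.abs(self.values) <= self.eps_phys
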