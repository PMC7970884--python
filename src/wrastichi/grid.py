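"""Core raster and vector containers.

A :class:`Grid` is a georeferenced 2-D cell array in a planar (projected)
frame.  Row 0 is the northern edge; ``origin_x``/``origin_y`` are the map
coordinates of the *outer* corner of cell ``(0, 0)`` (the north-west corner
of the raster), so cell ``(row, col)`` has its center at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

A :class:`FeatureLayer` is an ordered set of shapely geometries with
attribute records, all in the same planar frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from shapely.geometry.base import BaseGeometry

__all__ = ["Grid", "FeatureLayer", "GridAlignmentError"]

DEFAULT_NODATA = -9999.0


class GridAlignmentError(ValueError):
    """Raised when an operation requires exactly co-registered grids."""


@dataclass
class Grid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values
        2-D array.  Units depend on the layer: metres for elevation,
        degrees for slope/aspect, unitless integer codes for categories.
    origin_x, origin_y
        Map coordinates of the north-west corner of the raster.
    cell_size
        Map units per cell edge; must be > 0.  Cells are square.
    nodata
        Sentinel marking missing cells.
    crs_id
        Free-text identifier of the planar reference frame.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs_id: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col)."""
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of all cell-center coordinates, shape = grid shape."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    # -- masks ----------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean array of cells that are not nodata (NaN counts as nodata)."""
        vals = self.values
        mask = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask &= ~np.isnan(vals)
        return mask

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new grid sharing this grid's georeferencing."""
        g = replace(self, values=np.asarray(values))
        if nodata is not None:
            g.nodata = nodata
        return g

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are not co-registered: "
                f"{self.shape}@({self.origin_x},{self.origin_y},{self.cell_size}) vs "
                f"{other.shape}@({other.origin_x},{other.origin_y},{other.cell_size})"
            )

    def equals(self, other: "Grid") -> bool:
        """Cell-by-cell and georeferencing equality (nodata-aware)."""
        if not self.aligned_with(other):
            return False
        m1, m2 = self.valid_mask(), other.valid_mask()
        if not np.array_equal(m1, m2):
            return False
        return np.allclose(self.values[m1].astype(float), other.values[m2].astype(float))


@dataclass
class FeatureLayer:
    """Polygon / polyline features with per-feature attribute records."""

    features: list[tuple[BaseGeometry, dict[str, Any]]] = field(default_factory=list)
    crs_id: str = "local"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]

    def attribute(self, key: str) -> list[Any]:
        """Column of one attribute across features; KeyError if missing anywhere."""
        out = []
        for i, (_, attrs) in enumerate(self.features):
            if key not in attrs:
                raise KeyError(f"attribute {key!r} missing on feature {i}")
            out.append(attrs[key])
        return out
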