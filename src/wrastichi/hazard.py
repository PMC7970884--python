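"""Per-cell Hazard Index components: slope class Sn, exposure class En,
permeability class Pn, their cellwise sum, and the per-basin aggregate.

The hazard term expresses how strongly a basin cell's terrain favours
drainage of pollutants into the lake: steeper slopes, shore-facing
exposure and permeable soils all raise it.  Exposure is scored on the
three-level scale 5 (favourable to pollutant accumulation in the lake),
3 (neutral) and 1 (unfavourable), judged from the angle between a cell's
downslope direction and the bearing to the nearest lake shore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid
from .terrain import FLOWDIR_NODATA

__all__ = [
    "ReclassTable",
    "permeability_from_texture",
    "reclass_slope",
    "exposure_class",
    "hazard_sum",
    "basin_hazard",
]


@dataclass(frozen=True)
class ReclassTable:
    """Banded reclassification of a continuous metric into integer classes.

    ``breakpoints`` (strictly increasing) split the axis into
    ``len(breakpoints) + 1`` half-open bands [lo, hi); a value exactly on a
    breakpoint belongs to the upper band, and the top band is closed above.
    ``classes`` gives one class per band.
    """

    breakpoints: tuple[float, ...]
    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.breakpoints) + 1:
            raise ValueError(
                f"need {len(self.breakpoints) + 1} classes for "
                f"{len(self.breakpoints)} breakpoints, got {len(self.classes)}"
            )
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def lookup(self, values: np.ndarray | float) -> np.ndarray:
        idx = np.digitize(np.asarray(values, dtype=float), self.breakpoints)
        return np.asarray(self.classes)[idx]

    @classmethod
    def from_config(cls, entry: Mapping) -> "ReclassTable":
        return cls(tuple(entry["breakpoints"]), tuple(entry["classes"]))


def permeability_from_texture(soil: Grid, table: Mapping[int, int]) -> Grid:
    """Permeability class Pn per cell from soil texture-class codes.

    ``table`` maps every texture code occurring in the raster to its
    permeability class; unmapped codes raise with the offending codes listed.
    """
    valid = soil.valid_mask()
    codes = np.unique(soil.values[valid]).astype(int)
    missing = [int(c) for c in codes if int(c) not in table]
    if missing:
        raise KeyError(f"soil texture codes without a permeability class: {missing}")
    out = np.full(soil.shape, FLOWDIR_NODATA, dtype=np.int64)
    vals = soil.values.astype(int)
    for code in codes:
        out[valid & (vals == code)] = table[int(code)]
    g = soil.like(out)
    g.nodata = FLOWDIR_NODATA
    return g


def reclass_slope(slope_deg: Grid, table: ReclassTable) -> Grid:
    """Slope class Sn per cell from slope in degrees (banded lookup)."""
    valid = slope_deg.valid_mask()
    out = np.full(slope_deg.shape, FLOWDIR_NODATA, dtype=np.int64)
    out[valid] = table.lookup(slope_deg.values[valid].astype(float))
    g = slope_deg.like(out)
    g.nodata = FLOWDIR_NODATA
    return g


def exposure_class(aspect_cardinal: Grid, lake_mask: Grid) -> Grid:
    """Exposure class En in {1, 3, 5} relative to the nearest lake shore.

    For each cell, the bearing to the nearest lake cell is compared with the
    cell's downslope direction (the center bearing of its cardinal aspect
    class).  An angular difference below 45 degrees means the cell drains
    toward the lake (5, favourable to accumulation); above 135 degrees it
    drains away (1, unfavourable); in between, and for flat cells and lake
    cells themselves, the effect is neutral (3).  The symmetric band edges
    make a 180-degree aspect flip swap 5 and 1 exactly.
    """
    aspect_cardinal.require_aligned(lake_mask, "aspect and lake mask")
    lakes = lake_mask.values.astype(bool) & lake_mask.valid_mask()
    if not lakes.any():
        raise ValueError("empty lake mask")
    valid = aspect_cardinal.valid_mask()
    codes = aspect_cardinal.values.astype(int)

    idx = ndimage.distance_transform_edt(~lakes, return_distances=False,
                                         return_indices=True)
    lr, lc = idx[0], idx[1]
    rows, cols = np.indices(aspect_cardinal.shape)
    east = (lc - cols).astype(float)
    north = (rows - lr).astype(float)
    bearing = np.degrees(np.arctan2(east, north)) % 360.0

    aspect_deg = (codes - 1) * 45.0            # class centers: N=0, NE=45, ...
    delta = np.abs(aspect_deg - bearing) % 360.0
    delta = np.minimum(delta, 360.0 - delta)

    en = np.full(aspect_cardinal.shape, 3, dtype=np.int64)
    en[delta < 45.0] = 5
    en[delta > 135.0] = 1
    en[codes == 0] = 3                          # flat: neutral
    en[lakes] = 3                               # on the lake itself: neutral
    en[~valid] = FLOWDIR_NODATA
    g = aspect_cardinal.like(en)
    g.nodata = FLOWDIR_NODATA
    return g


def hazard_sum(sn: Grid, en: Grid, pn: Grid) -> Grid:
    """Cellwise hazard index Sn + En + Pn; nodata in any input propagates."""
    sn.require_aligned(en, "Sn and En")
    sn.require_aligned(pn, "Sn and Pn")
    valid = sn.valid_mask() & en.valid_mask() & pn.valid_mask()
    total = sn.values.astype(float) + en.values.astype(float) + pn.values.astype(float)
    out = np.where(valid, total, float(FLOWDIR_NODATA))
    g = sn.like(out)
    g.nodata = float(FLOWDIR_NODATA)
    return g


def basin_hazard(hi: Grid, basin_mask: Grid, how: str = "mean") -> float:
    """Aggregate the cellwise hazard index over one basin to a single value.

    ``how`` selects the aggregate: ``mean`` (default), ``median`` or
    ``mode`` (smallest value on ties).
    """
    hi.require_aligned(basin_mask, "hazard grid and basin mask")
    basin = basin_mask.values.astype(bool) & basin_mask.valid_mask()
    vals = hi.values[basin & hi.valid_mask()].astype(float)
    if vals.size == 0:
        raise ValueError("empty basin")
    if how == "mean":
        return float(vals.mean())
    if how == "median":
        return float(np.median(vals))
    if how == "mode":
        uniq, counts = np.unique(vals, return_counts=True)
        return float(uniq[np.argmax(counts)])
    raise ValueError(f"unknown aggregation {how!r}")
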