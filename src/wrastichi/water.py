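"""Delimitation of permanent water bodies from multispectral imagery.

The stage mirrors the classic remote-sensing recipe: compute the
Normalized Difference Water Index (NDWI, positive over open water) and
optionally a Tasseled-Cap wetness band, cluster the pixels without
supervision (Iso-Cluster, k-means family), keep the clusters whose mean
NDWI marks them as water, and vectorize the mask into lake polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import box
from skimage import measure
from sklearn.cluster import KMeans

from .grid import FeatureLayer, Grid

__all__ = ["BandStack", "ndwi", "tcw", "iso_cluster", "extract_water_mask",
           "mask_to_lakes"]

# Placeholder Tasseled-Cap wetness weights over the bands this package names.
# Sensor-calibrated coefficients differ per instrument; confirm before use.
DEFAULT_TCW_COEFFICIENTS: dict[str, float] = {
    "green": 0.2021, "red": 0.3102, "nir": 0.3072, "swir1": -0.6806,
}


@dataclass
class BandStack:
    """Named, co-registered reflectance bands (green and nir at minimum)."""

    bands: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.bands.values())
        for g in grids[1:]:
            grids[0].require_aligned(g, "bands")

    def __getitem__(self, name: str) -> Grid:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    @property
    def template(self) -> Grid:
        return next(iter(self.bands.values()))

    def valid_mask(self) -> np.ndarray:
        masks = [g.valid_mask() for g in self.bands.values()]
        return np.logical_and.reduce(masks)


def ndwi(green: Grid, nir: Grid) -> Grid:
    """(green - nir) / (green + nir), in [-1, 1]; zero-sum cells -> nodata."""
    green.require_aligned(nir, "green and nir bands")
    g = green.values.astype(float)
    n = nir.values.astype(float)
    total = g + n
    valid = green.valid_mask() & nir.valid_mask() & (total != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = (g - n) / total
    nodata = -9999.0
    out = np.where(valid, idx, nodata)
    result = green.like(out)
    result.nodata = nodata
    return result


def tcw(bands: BandStack, coefficients: Mapping[str, float] | None = None) -> Grid:
    """Tasseled-Cap wetness: per-cell weighted sum of the named bands.

    Coefficients are supplied via config; the shipped defaults are a
    placeholder the user must confirm for their sensor.
    """
    if coefficients is None:
        coefficients = DEFAULT_TCW_COEFFICIENTS
    missing = [b for b in coefficients if b not in bands]
    if missing:
        raise KeyError(f"TCW coefficients refer to missing bands: {missing}")
    template = bands.template
    out = np.zeros(template.shape, dtype=float)
    for name, coef in coefficients.items():
        out += float(coef) * bands[name].values.astype(float)
    valid = bands.valid_mask()
    nodata = -9999.0
    result = template.like(np.where(valid, out, nodata))
    result.nodata = nodata
    return result


def iso_cluster(bands: BandStack, k: int, seed: int) -> Grid:
    """Unsupervised spectral clustering of the pixel vectors into k classes.

    k-means with seeded k-means++ initialization, 50-iteration cap and a
    small relative-inertia tolerance; deterministic given the seed.  Labels
    are arbitrary in identity (0..k-1); evaluation should match labels.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    template = bands.template
    valid = bands.valid_mask()
    if not valid.any():
        raise ValueError("all-nodata band stack")
    X = np.stack([g.values[valid].astype(float) for g in bands.bands.values()], axis=1)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct spectral vectors")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=50,
                tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    out = np.full(template.shape, -1, dtype=np.int64)
    out[valid] = labels
    g = template.like(out)
    g.nodata = -1
    return g


def extract_water_mask(labels: Grid, ndwi_grid: Grid, threshold: float = 0.0) -> Grid:
    """Retain the clusters whose mean NDWI exceeds the threshold as water.

    Reproducible stand-in for the manual step of keeping the classes that
    define water bodies: any cluster with mean NDWI above ``threshold``
    (default 0.0) contributes to the boolean water mask.  If no cluster
    qualifies the mask is empty and a warning is issued.
    """
    labels.require_aligned(ndwi_grid, "cluster labels and NDWI")
    valid = labels.valid_mask() & ndwi_grid.valid_mask()
    water = np.zeros(labels.shape, dtype=bool)
    any_hit = False
    for lab in np.unique(labels.values[valid]):
        sel = valid & (labels.values == lab)
        if ndwi_grid.values[sel].astype(float).mean() > threshold:
            water |= sel
            any_hit = True
    if not any_hit:
        warnings.warn("no cluster exceeds the NDWI threshold; water mask is empty",
                      stacklevel=2)
    g = labels.like(water.astype(np.uint8))
    g.nodata = 255
    return g


def mask_to_lakes(mask: Grid, min_cells: int = 3) -> FeatureLayer:
    """Vectorize a boolean water mask into lake polygons.

    4-connected components with at least ``min_cells`` cells become polygon
    features with a unique ``lake_id`` and a ``n_cells`` attribute.
    """
    water = mask.values.astype(bool) & mask.valid_mask()
    comp = measure.label(water, connectivity=1)
    features = []
    lake_id = 0
    for region in measure.regionprops(comp):
        if region.area < min_cells:
            continue
        lake_id += 1
        cells = [
            box(
                mask.origin_x + c * mask.cell_size,
                mask.origin_y - (r + 1) * mask.cell_size,
                mask.origin_x + (c + 1) * mask.cell_size,
                mask.origin_y - r * mask.cell_size,
            )
            for r, c in region.coords
        ]
        poly = shapely.unary_union(cells)
        features.append((poly, {"lake_id": lake_id, "n_cells": int(region.area)}))
    return FeatureLayer(features, crs_id=mask.crs_id)
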