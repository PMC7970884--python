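"""Reading, writing and aligning the geospatial layers the pipeline touches.

Rasters travel as single-band GeoTIFF: the pixel data plus the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) written
and parsed through :mod:`tifffile`.  Vectors travel as GeoJSON with planar
coordinates.  Alignment between grids must be exact — resampling is out of
scope; inputs are either pre-aligned or produced by this package.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Any

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import FeatureLayer, Grid, GridAlignmentError

__all__ = [
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "rasterize",
    "zonal_fraction",
    "fraction_in_layer",
]

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_DESCRIPTION = 270


def write_raster(grid: Grid, path: str | os.PathLike) -> None:
    """Write a grid as a single-band GeoTIFF.

    Georeferencing goes into ModelPixelScale/ModelTiepoint, the nodata
    sentinel into GDAL_NODATA, and the crs identifier into the image
    description, so :func:`read_raster` round-trips all fields.
    """
    desc = json.dumps({"crs_id": grid.crs_id})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values, description=desc, extratags=extratags)


def read_raster(path: str | os.PathLike) -> Grid:
    """Read a single-band GeoTIFF written by this package or a compatible tool.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    multi-band raster (band selection is not supported).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(
                f"expected a single-band raster, got array of shape {values.shape}; "
                "split bands into separate files"
            )
        tags = page.tags
        cell_size = 1.0
        origin_x = origin_y = 0.0
        nodata = Grid.__dataclass_fields__["nodata"].default
        crs_id = "local"
        if _TAG_PIXEL_SCALE in tags:
            cell_size = float(tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            origin_x, origin_y = float(tp[3]), float(tp[4])
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value.strip("\x00").strip()
            nodata = float(raw)
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
        if _TAG_DESCRIPTION in tags:
            try:
                crs_id = json.loads(tags[_TAG_DESCRIPTION].value).get("crs_id", "local")
            except (json.JSONDecodeError, AttributeError):
                pass
    return Grid(values, origin_x=origin_x, origin_y=origin_y, cell_size=cell_size,
                nodata=nodata, crs_id=crs_id)


def write_vector(layer: FeatureLayer, path: str | os.PathLike) -> None:
    """Write a feature layer as GeoJSON (planar coordinates)."""
    fc = {
        "type": "FeatureCollection",
        "crs_id": layer.crs_id,
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
            for geom, attrs in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_vector(path: str | os.PathLike) -> FeatureLayer:
    if not os.path.exists(path):
        raise FileNotFoundError(f"vector file not found: {path}")
    with open(path) as fh:
        fc = json.load(fh)
    features = [
        (shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in fc.get("features", [])
    ]
    return FeatureLayer(features, crs_id=fc.get("crs_id", "local"))


def rasterize(layer: FeatureLayer, template: Grid, attribute: str) -> Grid:
    """Burn a polygon layer's attribute onto the template grid.

    Cell-center rule: a cell takes the attribute of the polygon covering its
    center; cells covered by no polygon are nodata.  Where polygons overlap
    the **last-listed** feature wins (stable, documented tie-break).
    """
    if layer.crs_id != template.crs_id:
        raise GridAlignmentError(
            f"layer crs {layer.crs_id!r} != template crs {template.crs_id!r}"
        )
    values = layer.attribute(attribute)  # raises KeyError if missing anywhere
    xs, ys = template.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    out = np.full(template.shape, template.nodata, dtype=float)
    flat = out.ravel()
    for (geom, _), val in zip(layer.features, values):
        # covers (not contains): centers on a polygon edge belong to it
        hit = shapely.covers(geom, pts)
        flat[hit] = val
    return template.like(flat.reshape(template.shape))


def zonal_fraction(category_grid: Grid, zone_mask: Grid, category: float) -> float:
    """Fraction of a zone's valid cells carrying one category code.

    Returns ``(# zone cells == category) / (# zone cells not nodata)``;
    an empty zone yields 0.0 with a warning.
    """
    category_grid.require_aligned(zone_mask, "category grid and zone mask")
    zone = zone_mask.values.astype(bool) & zone_mask.valid_mask()
    valid = zone & category_grid.valid_mask()
    n = int(valid.sum())
    if n == 0:
        warnings.warn("zonal_fraction: empty zone, returning 0.0", stacklevel=2)
        return 0.0
    return float(np.count_nonzero(category_grid.values[valid] == category)) / n


def fraction_in_layer(basin_polygon: BaseGeometry, areas: FeatureLayer) -> float:
    """Area fraction of a basin polygon inside the union of a polygon layer."""
    if basin_polygon.area <= 0:
        raise ValueError("basin polygon has zero area")
    if len(areas) == 0:
        return 0.0
    union = shapely.unary_union(areas.geometries())
    return float(basin_polygon.intersection(union).area / basin_polygon.area)


def mask_grid(template: Grid, mask: np.ndarray) -> Grid:
    """Boolean mask as a uint8 grid sharing the template's georeferencing."""
    g = template.like(np.asarray(mask, dtype=np.uint8))
    g.nodata = 255
    return g
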