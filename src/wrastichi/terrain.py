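"""Terrain derivatives and D8 hydrology from a DEM.

Slope and aspect use Horn's 3x3 finite-difference kernel (the method behind
the common GIS surface tools); flow routing is single-direction D8 with a
deterministic tie-break and a breadth-first plateau rule, so that every
cell's flow path terminates and per-lake hydrographic basins are well
defined.  Lake cells are treated as sinks during pit filling so basins
terminate at the lakes they drain to.
"""

from __future__ import annotations

import heapq
from collections import deque

import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = [
    "compute_slope",
    "compute_aspect",
    "reclass_aspect_cardinal",
    "fill_pits",
    "d8_flow_direction",
    "delineate_basin",
    "FLAT",
    "OUTLET",
    "D8_OFFSETS",
    "ASPECT_CLASSES",
]

FLAT = -1.0          # aspect sentinel for cells below the slope threshold
OUTLET = -1          # flow-direction code: drains off-grid / terminal pit
FLOWDIR_NODATA = -9

# D8 neighbour order also used for tie-breaking: E, SE, S, SW, W, NW, N, NE
D8_OFFSETS: list[tuple[int, int]] = [
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
]
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])

# cardinal aspect classes (codes), FLAT -> 0
ASPECT_CLASSES = {0: "FLAT", 1: "N", 2: "NE", 3: "E", 4: "SE",
                  5: "S", 6: "SW", 7: "W", 8: "NW"}


def _filled_elevations(dem: Grid) -> np.ndarray:
    """Float elevations with nodata cells replaced by their nearest valid value.

    Gives clamped-neighbourhood semantics at internal nodata edges; callers
    mask outputs back to the valid footprint.
    """
    valid = dem.valid_mask()
    if valid.sum() < 9 or min(dem.shape) < 3:
        raise ValueError("DEM needs at least a 3x3 block of valid cells")
    z = dem.values.astype(float).copy()
    if not valid.all():
        idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                             return_indices=True)
        z = z[tuple(idx)]
    return z


def _horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward) by Horn's kernel, edge-clamped."""
    z = np.pad(_filled_elevations(dem), 1, mode="edge")
    c = dem.cell_size
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * c)
    gy_north = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * c)
    return gx, gy_north


def compute_slope(dem: Grid) -> Grid:
    """Slope in degrees from Horn's 3x3 gradient; border cells edge-clamped."""
    gx, gy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    out = np.where(dem.valid_mask(), slope, dem.nodata)
    return dem.like(out)


def compute_aspect(dem: Grid, flat_tol: float = 0.01) -> Grid:
    """Downslope bearing in degrees clockwise from north; flat cells -> -1.

    ``flat_tol`` is a slope threshold in degrees below which a cell is
    declared flat (default 0.01 deg).
    """
    gx, gy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    bearing = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(slope < flat_tol, FLAT, bearing)
    out = np.where(dem.valid_mask(), aspect, dem.nodata)
    return dem.like(out)


def reclass_aspect_cardinal(aspect: Grid) -> Grid:
    """Reclass the 0-360 aspect into the nine cardinal classes.

    N covers [337.5, 360) plus [0, 22.5); every other octant is a 45-degree
    sector.  Flat cells (-1) map to class 0 (FLAT).  Codes follow
    :data:`ASPECT_CLASSES`.
    """
    valid = aspect.valid_mask()
    a = aspect.values.astype(float)
    vals = a[valid]
    bad = vals[(vals != FLAT) & ((vals < 0) | (vals >= 360))]
    if bad.size:
        raise ValueError(f"aspect values outside [0,360) or -1: e.g. {bad[0]}")
    octant = (np.floor(((a + 22.5) % 360.0) / 45.0).astype(int) + 1)
    codes = np.where(a == FLAT, 0, octant)
    out = np.where(valid, codes, FLOWDIR_NODATA)
    g = aspect.like(out.astype(np.int64))
    g.nodata = FLOWDIR_NODATA
    return g


def fill_pits(dem: Grid, lake_mask: Grid | None = None) -> Grid:
    """Priority-flood depression filling with minimal raising.

    After filling, every valid cell has a non-ascending 8-connected path to
    the grid boundary or to a lake cell.  Lake cells act as sinks: they keep
    their elevation and absorb drainage, so later basin delineation stops at
    lakes instead of draining through them.
    """
    valid = dem.valid_mask()
    z = dem.values.astype(float)
    out = z.copy()
    nr, nc = dem.shape
    closed = ~valid
    lakes = np.zeros_like(valid)
    if lake_mask is not None:
        dem.require_aligned(lake_mask, "DEM and lake mask")
        lakes = lake_mask.values.astype(bool) & valid

    heap: list[tuple[float, int, int]] = []
    boundary = np.zeros_like(valid)
    boundary[0, :] = boundary[-1, :] = boundary[:, 0] = boundary[:, -1] = True
    # cells adjacent to nodata drain into the nodata void as well
    if not valid.all():
        boundary |= ndimage.binary_dilation(~valid, structure=np.ones((3, 3)))
    seeds = (boundary | lakes) & valid & ~closed
    for r, c in zip(*np.nonzero(seeds)):
        heapq.heappush(heap, (z[r, c], int(r), int(c)))
        closed[r, c] = True

    while heap:
        elev, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                if lakes[rr, cc]:
                    out[rr, cc] = z[rr, cc]   # sinks are never raised
                else:
                    out[rr, cc] = max(z[rr, cc], elev)
                heapq.heappush(heap, (out[rr, cc], rr, cc))
    return dem.like(np.where(valid, out, dem.nodata))


def d8_flow_direction(dem_filled: Grid) -> Grid:
    """D8 steepest-descent flow directions on a pit-filled DEM.

    Each cell points to the neighbour with the largest drop per unit
    distance (diagonals weighted by sqrt(2)); ties go to the first neighbour
    in the fixed order E, SE, S, SW, W, NW, N, NE.  Cells with no lower
    neighbour on the grid boundary are outlets; interior flats are resolved
    by breadth-first distance to the nearest draining (spill) cell across
    equal elevations.  Codes: 0..7 index :data:`D8_OFFSETS`, -1 = outlet.
    """
    valid = dem_filled.valid_mask()
    z = dem_filled.values.astype(float)
    nr, nc = dem_filled.shape
    fd = np.full((nr, nc), FLOWDIR_NODATA, dtype=np.int64)

    # steepest descent, vectorised over the 8 shifted copies
    best_grad = np.zeros((nr, nc))
    pad = np.pad(np.where(valid, z, np.inf), 1, constant_values=np.inf)
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        zn = pad[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
        grad = (z - zn) / (_D8_DIST[k] * dem_filled.cell_size)
        take = valid & (grad > best_grad + 0)
        # strict > keeps the earliest neighbour in the tie-break order
        fd[take] = k
        best_grad = np.where(take, grad, best_grad)

    unresolved = valid & (fd == FLOWDIR_NODATA)

    # plateau resolution: BFS from spill cells over equal-elevation flats
    queue: deque[tuple[int, int]] = deque()
    on_boundary = np.zeros_like(valid)
    on_boundary[0, :] = on_boundary[-1, :] = on_boundary[:, 0] = on_boundary[:, -1] = True
    for r, c in zip(*np.nonzero(unresolved & on_boundary)):
        fd[r, c] = OUTLET
        unresolved[r, c] = False
        queue.append((int(r), int(c)))
    # flats adjacent to an equal-elevation cell that already drains
    for r, c in zip(*np.nonzero(unresolved)):
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]
                    and fd[rr, cc] != FLOWDIR_NODATA and not unresolved[rr, cc]
                    and z[rr, cc] == z[r, c]):
                fd[r, c] = k
                unresolved[r, c] = False
                queue.append((int(r), int(c)))
                break
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < nr and 0 <= cc < nc and unresolved[rr, cc]
                    and z[rr, cc] == z[r, c]):
                # neighbour points back toward (r, c): opposite direction
                fd[rr, cc] = (k + 4) % 8
                unresolved[rr, cc] = False
                queue.append((rr, cc))
    # anything left is an isolated pit (e.g. a lake floor): terminal
    fd[unresolved] = OUTLET

    g = dem_filled.like(fd)
    g.nodata = FLOWDIR_NODATA
    return g


def delineate_basin(flowdir: Grid, lake_mask: Grid) -> Grid:
    """All cells whose D8 path reaches any lake cell, lake cells included.

    Returns a uint8 boolean grid aligned with the inputs.
    """
    flowdir.require_aligned(lake_mask, "flow directions and lake mask")
    lakes = lake_mask.values.astype(bool) & lake_mask.valid_mask()
    if not lakes.any():
        raise ValueError("empty lake mask")
    nr, nc = flowdir.shape
    fd = flowdir.values
    valid = flowdir.valid_mask()

    # reverse adjacency: children[target] = cells draining into it
    basin = lakes.copy()
    stack = [(int(r), int(c)) for r, c in zip(*np.nonzero(lakes))]
    # precompute, for every cell, which neighbours drain INTO it
    while stack:
        r, c = stack.pop()
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc] and not basin[rr, cc]:
                # neighbour drains to (r, c) iff its code points opposite to k
                if fd[rr, cc] == (k + 4) % 8:
                    basin[rr, cc] = True
                    stack.append((rr, cc))
    g = flowdir.like(basin.astype(np.uint8))
    g.nodata = 255
    return g
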