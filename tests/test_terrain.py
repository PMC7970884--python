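"""Slope/aspect against analytic planes; pit filling, D8 routing and basin
delineation against brute-force oracles."""

import numpy as np
import pytest

from wrastichi import terrain
from wrastichi.grid import Grid
from wrastichi.terrain import D8_OFFSETS, FLAT, OUTLET


def plane_grid(a_east=0.0, a_north=0.0, shape=(12, 15), cell=2.0):
    """DEM z = a_east * x + a_north * y, y increasing northward."""
    rows, cols = np.indices(shape)
    x = (cols + 0.5) * cell
    y = shape[0] * cell - (rows + 0.5) * cell
    return Grid(a_east * x + a_north * y, cell_size=cell, origin_y=shape[0] * cell)


def lake_grid(mask, template):
    g = template.like(np.asarray(mask, dtype=np.uint8))
    g.nodata = 255
    return g


class TestSlopeAspect:
    def test_constant_dem_zero_slope_flat_aspect(self):
        dem = Grid(np.full((6, 6), 3.0))
        assert (terrain.compute_slope(dem).values == 0).all()
        assert (terrain.compute_aspect(dem).values == FLAT).all()

    @pytest.mark.parametrize("a_east,a_north,slope_deg", [
        (0.1, 0.0, np.degrees(np.arctan(0.1))),
        (1.0, 1.0, np.degrees(np.arctan(np.sqrt(2)))),
        (0.0, 0.3, np.degrees(np.arctan(0.3))),
    ])
    def test_slope_matches_analytic_plane(self, a_east, a_north, slope_deg):
        dem = plane_grid(a_east, a_north)
        s = terrain.compute_slope(dem).values
        assert np.allclose(s[1:-1, 1:-1], slope_deg, atol=1e-6)

    @pytest.mark.parametrize("a_east,a_north,bearing", [
        (-1.0, 0.0, 90.0),    # descending east
        (1.0, 1.0, 225.0),    # descending south-west
        (0.0, 1.0, 180.0),    # descending south
        (1.0, 0.0, 270.0),    # descending west
    ])
    def test_aspect_bearing_on_planes(self, a_east, a_north, bearing):
        dem = plane_grid(a_east, a_north)
        a = terrain.compute_aspect(dem).values
        assert np.allclose(a[1:-1, 1:-1], bearing, atol=1e-6)

    def test_all_nodata_dem_errors(self):
        dem = Grid(np.full((5, 5), -9999.0), nodata=-9999.0)
        with pytest.raises(ValueError):
            terrain.compute_slope(dem)


class TestAspectReclass:
    @pytest.mark.parametrize("deg,code", [
        (0.0, 1), (22.4, 1), (337.5, 1),      # N wraps around north
        (100.0, 3),                            # [67.5, 112.5) -> E
        (45.0, 2), (225.0, 6), (292.5, 8), (292.4, 7),  # sector edge -> upper band
        (FLAT, 0),
    ])
    def test_sector_assignment(self, deg, code):
        g = Grid(np.full((3, 3), float(deg)))
        assert (terrain.reclass_aspect_cardinal(g).values == code).all()

    def test_out_of_range_errors(self):
        g = Grid(np.full((3, 3), 361.0))
        with pytest.raises(ValueError):
            terrain.reclass_aspect_cardinal(g)

    def test_every_octant_is_45_degrees(self):
        degs = np.arange(0.0, 360.0, 0.5)
        g = Grid(degs.reshape(1, -1))
        codes = terrain.reclass_aspect_cardinal(g).values.ravel()
        # each of the 8 direction codes covers exactly 90 of the 720 samples
        for code in range(1, 9):
            assert (codes == code).sum() == 90


class TestFillPits:
    def test_single_cell_depression_raised_to_spill(self):
        dem_vals = np.full((5, 5), 10.0)
        dem_vals[2, 2] = 4.0
        dem = Grid(dem_vals)
        filled = terrain.fill_pits(dem).values
        assert filled[2, 2] == 10.0            # raised exactly to spill level
        changed = filled != dem_vals
        assert changed.sum() == 1 and changed[2, 2]

    def test_drained_dem_unchanged(self):
        dem = plane_grid(0.2, 0.1, shape=(8, 8))
        filled = terrain.fill_pits(dem)
        assert np.allclose(filled.values, dem.values)

    def test_random_dem_has_no_interior_pits(self):
        rng = np.random.default_rng(5)
        dem = Grid(rng.normal(size=(15, 15)) * 3)
        filled = terrain.fill_pits(dem).values
        for r in range(1, 14):
            for c in range(1, 14):
                neigh = [filled[r + dr, c + dc] for dr, dc in D8_OFFSETS]
                assert filled[r, c] >= min(neigh) - 1e-12

    def test_lake_cells_never_raised(self):
        dem_vals = np.full((7, 7), 10.0)
        dem_vals[3, 3] = -2.0
        dem = Grid(dem_vals)
        lakes = np.zeros((7, 7), bool)
        lakes[3, 3] = True
        filled = terrain.fill_pits(dem, lake_grid(lakes, dem)).values
        assert filled[3, 3] == -2.0


class TestD8:
    def test_plane_points_east(self):
        dem = plane_grid(-1.0, 0.0)  # descending east
        fd = terrain.d8_flow_direction(terrain.fill_pits(dem)).values
        assert (fd[:, :-1] == 0).all()          # code 0 = E
        assert (fd[:, -1] == OUTLET).all()      # last column drains off-grid

    def test_cone_routes_inward_to_center(self):
        rows, cols = np.indices((11, 11))
        dem = Grid(np.hypot(rows - 5, cols - 5).astype(float), origin_y=11.0)
        lakes = np.zeros((11, 11), bool)
        lakes[5, 5] = True          # sink at the apex keeps the pit terminal
        fd = terrain.d8_flow_direction(
            terrain.fill_pits(dem, lake_grid(lakes, dem))).values
        assert fd[5, 5] == OUTLET
        # steepest-descent check per cell: chosen neighbour has the max drop
        z = dem.values
        dist = np.array([1, np.sqrt(2)] * 4)[[0, 1, 0, 1, 0, 1, 0, 1]]
        for r in range(1, 10):
            for c in range(1, 10):
                if (r, c) == (5, 5):
                    continue
                grads = [(z[r, c] - z[r + dr, c + dc]) / d
                         for (dr, dc), d in zip(D8_OFFSETS, dist)]
                k = fd[r, c]
                assert grads[k] == pytest.approx(max(grads))

    def test_plateau_drains_toward_spill(self):
        # flat plateau with one drained edge cell: all plateau cells resolve
        dem_vals = np.full((5, 7), 5.0)
        dem_vals[:, 6] = 0.0       # drained eastern edge
        dem = Grid(dem_vals)
        fd = terrain.d8_flow_direction(dem).values
        # every plateau cell eventually reaches the low edge
        for r in range(5):
            rr, cc = r, 0
            for _ in range(50):
                k = fd[rr, cc]
                if k == OUTLET:
                    break
                dr, dc = D8_OFFSETS[k]
                rr, cc = rr + dr, cc + dc
            assert cc == 6 or fd[rr, cc] == OUTLET
            assert dem_vals[rr, cc] == 0.0 or (rr in (0, 4) or cc in (0, 6))


def follow_arrows_basin(fd, lakes):
    """Brute-force oracle: walk the D8 arrows from every cell."""
    nr, nc = fd.shape
    out = np.zeros((nr, nc), bool)
    for r in range(nr):
        for c in range(nc):
            rr, cc = r, c
            for _ in range(nr * nc):
                if lakes[rr, cc]:
                    out[r, c] = True
                    break
                k = fd[rr, cc]
                if k == OUTLET:
                    break
                dr, dc = D8_OFFSETS[k]
                rr, cc = rr + dr, cc + dc
    return out


class TestBasin:
    def test_cone_with_central_lake_drains_whole_grid(self):
        rows, cols = np.indices((11, 11))
        dem = Grid(np.hypot(rows - 5, cols - 5).astype(float), origin_y=11.0)
        lakes = np.zeros((11, 11), bool)
        lakes[5, 5] = True
        lm = lake_grid(lakes, dem)
        fd = terrain.d8_flow_direction(terrain.fill_pits(dem, lm))
        basin = terrain.delineate_basin(fd, lm)
        assert basin.values.astype(bool).all()

    def test_two_valleys_split_by_ridge(self):
        # ridge along the middle column; lake in the west valley
        rows, cols = np.indices((9, 11))
        dem = Grid(-np.abs(cols - 5).astype(float) + 5.0, origin_y=9.0)
        lakes = np.zeros((9, 11), bool)
        lakes[4, 0] = True
        lm = lake_grid(lakes, dem)
        fd = terrain.d8_flow_direction(terrain.fill_pits(dem, lm))
        basin = terrain.delineate_basin(fd, lm).values.astype(bool)
        assert not basin[:, 6:].any()           # east valley excluded

    def test_edge_lake_draining_outward(self):
        dem = plane_grid(-1.0, 0.0, shape=(6, 6))  # everything drains east
        lakes = np.zeros((6, 6), bool)
        lakes[3, 0] = True                          # lake on the west edge
        lm = lake_grid(lakes, dem)
        fd = terrain.d8_flow_direction(terrain.fill_pits(dem, lm))
        basin = terrain.delineate_basin(fd, lm).values.astype(bool)
        assert basin.sum() == 1 and basin[3, 0]

    def test_matches_follow_arrows_oracle_on_random_dems(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            dem = Grid(rng.normal(size=(30, 30)).cumsum(axis=1)
                       + rng.normal(size=(30, 30)), origin_y=30.0)
            lakes = np.zeros((30, 30), bool)
            lakes[rng.integers(3, 27), rng.integers(3, 27)] = True
            lm = lake_grid(lakes, dem)
            fd = terrain.d8_flow_direction(terrain.fill_pits(dem, lm))
            basin = terrain.delineate_basin(fd, lm).values.astype(bool)
            assert np.array_equal(basin, follow_arrows_basin(fd.values, lakes))

    def test_disjoint_lakes_disjoint_basins(self):
        rows, cols = np.indices((10, 21))
        # two cones separated by a ridge at column 10
        d1 = np.hypot(rows - 5, cols - 3)
        d2 = np.hypot(rows - 5, cols - 17)
        dem = Grid(np.minimum(d1, d2).astype(float), origin_y=10.0)
        masks = []
        for cc in (3, 17):
            lakes = np.zeros((10, 21), bool)
            lakes[5, cc] = True
            lm = lake_grid(lakes, dem)
            fd = terrain.d8_flow_direction(terrain.fill_pits(dem, lm))
            masks.append(terrain.delineate_basin(fd, lm).values.astype(bool))
        assert not (masks[0] & masks[1]).any()
        assert not masks[0][:, 12:].any()
        assert not masks[1][:, :9].any()

    def test_empty_lake_mask_errors(self):
        dem = plane_grid(1.0, 0.0, shape=(5, 5))
        fd = terrain.d8_flow_direction(terrain.fill_pits(dem))
        with pytest.raises(ValueError):
            terrain.delineate_basin(fd, lake_grid(np.zeros((5, 5), bool), dem))
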