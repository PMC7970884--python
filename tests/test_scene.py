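"""The synthetic catchment generator: determinism, terrain construction,
driver-coupled land use, spectral separability and pressure layers."""

import numpy as np
import pytest

from wrastichi import terrain, water
from wrastichi.geodata_io import zonal_fraction
from wrastichi.grid import Grid
from wrastichi.scene import (LANDUSE_LAW, FACILITY_RATE, SceneSpec, SceneTruth,
                             generate_bands, generate_dem,
                             generate_facilities_routes, generate_landuse,
                             generate_scene)


def local_minima(values):
    """Exhaustive scan for cells strictly below all 8 neighbours."""
    nr, nc = values.shape
    out = []
    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            neigh = values[r - 1:r + 2, c - 1:c + 2].copy()
            v = neigh[1, 1]
            neigh[1, 1] = np.inf
            if v < neigh.min():
                out.append((r, c))
    return out


class TestGenerateDem:
    def test_single_depression_unique_minimum_region(self):
        spec = SceneSpec(shape=(40, 40), n_lakes=1, drivers=[0.5],
                         dem_noise=0.0, seed=1)
        dem, wm, centers = generate_dem(spec)
        water_cells = wm.values.astype(bool)
        assert dem.values[water_cells].max() < dem.values[~water_cells].min()

    def test_n_lakes_disjoint_minima(self):
        spec = SceneSpec(shape=(80, 80), n_lakes=3, drivers=[0.2, 0.5, 0.8],
                         dem_noise=0.0, seed=2)
        dem, wm, centers = generate_dem(spec)
        assert len(centers) == 3
        from skimage import measure
        ncomp = measure.label(wm.values.astype(bool), connectivity=1).max()
        assert ncomp == 3

    def test_determinism_same_seed(self):
        spec = SceneSpec(shape=(40, 40), n_lakes=2, drivers=[0.3, 0.7], seed=9)
        d1, w1, c1 = generate_dem(spec)
        d2, w2, c2 = generate_dem(spec)
        assert np.array_equal(d1.values, d2.values)
        assert c1 == c2

    def test_infeasible_density_errors(self):
        spec = SceneSpec(shape=(20, 20), n_lakes=30,
                         drivers=[0.5] * 30, seed=0)
        with pytest.raises(ValueError):
            generate_dem(spec)


class TestTruthBasins:
    def test_basins_match_independent_d8_run(self):
        """Truth partition agrees with flow routing recomputed from scratch
        on the noise-free DEM."""
        spec = SceneSpec(shape=(60, 60), n_lakes=2, drivers=[0.2, 0.8],
                         dem_noise=0.0, seed=4)
        sc = generate_scene(spec)
        filled = terrain.fill_pits(sc.dem, sc.truth.water_mask)
        fd = terrain.d8_flow_direction(filled)
        for lake_id in (1, 2):
            lm = sc.truth.basin_mask(lake_id)
            lake_cells = (sc.truth.basin_id.values == lake_id) & \
                sc.truth.water_mask.values.astype(bool)
            lg = sc.dem.like(lake_cells.astype(np.uint8))
            lg.nodata = 255
            basin = terrain.delineate_basin(fd, lg)
            assert np.array_equal(basin.values.astype(bool),
                                  lm.values.astype(bool))

    def test_single_lake_basin_covers_grid(self):
        spec = SceneSpec(shape=(40, 40), n_lakes=1, drivers=[0.5],
                         dem_noise=0.0, seed=5)
        sc = generate_scene(spec)
        assert (sc.truth.basin_id.values == 1).all()


class TestGenerateLanduse:
    def scene(self, drivers, seed=6, shape=(64, 64)):
        return generate_scene(SceneSpec(shape=shape, n_lakes=len(drivers),
                                        drivers=drivers, dem_noise=0.0,
                                        seed=seed))

    def test_zero_driver_fully_natural(self):
        sc = self.scene([0.0])
        lu = sc.landuse.values
        land = ~sc.truth.water_mask.values.astype(bool)
        assert (lu[land] == sc.spec.landuse_codes["natural_vegetation"]).all()

    def test_max_driver_hits_target_fractions(self):
        sc = self.scene([1.0], shape=(80, 80))
        basin = sc.truth.basin_mask(1)
        n = int(basin.values.sum())
        for cat, target in LANDUSE_LAW.items():
            frac = zonal_fraction(sc.landuse, basin,
                                  sc.spec.landuse_codes[cat])
            sigma = np.sqrt(target * (1 - target) / n)
            # water cells inside the basin dilute the fraction slightly
            assert abs(frac - target) < 3 * sigma + 0.02

    def test_driver_ordering_preserved(self):
        sc = self.scene([0.05, 0.95], shape=(80, 80), seed=8)
        fracs = []
        for lake_id in (1, 2):
            basin = sc.truth.basin_mask(lake_id)
            fracs.append(zonal_fraction(sc.landuse, basin,
                                        sc.spec.landuse_codes["agricultural"]))
        assert fracs[0] < fracs[1]


class TestGenerateBands:
    def test_zero_noise_ndwi_sign_separates_water(self):
        spec = SceneSpec(shape=(40, 40), n_lakes=1, drivers=[0.5],
                         dem_noise=0.0, band_noise=0.0, seed=10)
        sc = generate_scene(spec)
        nd = water.ndwi(sc.bands["green"], sc.bands["nir"]).values
        w = sc.truth.water_mask.values.astype(bool)
        assert (nd[w] > 0).all()
        assert (nd[~w] < 0).all()

    def test_low_noise_recovery_by_delineation(self, quiet_scene):
        sc = quiet_scene
        stack = water.BandStack(sc.bands)
        nd = water.ndwi(sc.bands["green"], sc.bands["nir"])
        labels = water.iso_cluster(stack, k=2, seed=1)
        mask = water.extract_water_mask(labels, nd).values.astype(bool)
        truth = sc.truth.water_mask.values.astype(bool)
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.99


class TestFacilitiesRoutes:
    def stripe_truth(self, n_basins, width=8, height=4, drivers=None):
        """Many thin stripe basins for rate-recovery checks."""
        shape = (height, n_basins * width)
        basin = np.zeros(shape, dtype=np.int64)
        for i in range(n_basins):
            basin[:, i * width:(i + 1) * width] = i + 1
        bid = Grid(basin, origin_y=float(height))
        bid.nodata = -1
        wm = bid.like(np.zeros(shape, dtype=np.uint8))
        wm.nodata = 255
        drivers = (np.full(n_basins, 0.5) if drivers is None
                   else np.asarray(drivers, dtype=float))
        return SceneTruth(drivers=drivers, water_mask=wm, basin_id=bid,
                          lake_centers=[])

    def test_zero_driver_zero_facilities(self):
        truth = self.stripe_truth(10, drivers=np.zeros(10))
        spec = SceneSpec(shape=truth.basin_id.shape, n_lakes=10, seed=0)
        fac, routes = generate_facilities_routes(spec, truth)
        assert len(fac) == 0 and len(routes) == 0

    def test_poisson_rate_recovered_over_many_basins(self):
        n = 500
        d = 0.6
        truth = self.stripe_truth(n, drivers=np.full(n, d))
        spec = SceneSpec(shape=truth.basin_id.shape, n_lakes=n, seed=3)
        fac, _ = generate_facilities_routes(spec, truth)
        n_ind = sum(1 for _, a in fac if a["kind"] == "industrial")
        lam = FACILITY_RATE * d
        sigma = np.sqrt(n * lam)
        assert abs(n_ind - n * lam) < 3 * sigma

    def test_deterministic_given_seed(self):
        truth = self.stripe_truth(20)
        spec = SceneSpec(shape=truth.basin_id.shape, n_lakes=20, seed=11)
        f1, r1 = generate_facilities_routes(spec, truth)
        f2, r2 = generate_facilities_routes(spec, truth)
        assert len(f1) == len(f2) and len(r1) == len(r2)
        for (g1, a1), (g2, a2) in zip(f1, f2):
            assert g1.equals(g2) and a1 == a2


class TestSceneDeterminism:
    def test_identical_spec_identical_scene(self):
        spec = SceneSpec(shape=(48, 48), n_lakes=2, seed=21)
        s1, s2 = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(s1.dem.values, s2.dem.values)
        assert np.array_equal(s1.landuse.values, s2.landuse.values)
        assert np.array_equal(s1.soil.values, s2.soil.values)
        assert np.array_equal(s1.truth.drivers, s2.truth.drivers)
        assert len(s1.facilities) == len(s2.facilities)

    def test_bad_drivers_rejected(self):
        with pytest.raises(ValueError):
            generate_scene(SceneSpec(n_lakes=2, drivers=[0.5], seed=0))
        with pytest.raises(ValueError):
            generate_scene(SceneSpec(n_lakes=1, drivers=[1.5], seed=0))
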