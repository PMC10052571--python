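"""Direct/diffuse interception, occlusion and the radiation records."""

import numpy as np
import pytest

from phytocanopy.geometry import TriangleSet
from phytocanopy.radiation import (SkyModel, diffuse_interception, direct_interception,
                                   hourly_records, occluded, records_to_frame,
                                   split_direct_diffuse)
from phytocanopy.solar import SolarGeometry, sun_position

from conftest import naive_ray_occluded, single_facet_scene


def overhead_sun(zenith=0.0, azimuth=180.0):
    return SolarGeometry(latitude=0.0, doy=80, hour=12.0, zenith=zenith,
                         azimuth=azimuth, declination=0.0, sunrise=6.0, sunset=18.0)


HORIZ = np.array([[0, 0, 100], [20, 0, 100], [0, 20, 100]], float)


class TestDirect:
    def test_normal_incidence_flux_density(self):
        scene = single_facet_scene(HORIZ)
        flux, lit = direct_interception(scene, overhead_sun(), 1000.0)
        area_m2 = scene.areas[0] * 1e-4
        assert lit[0]
        assert flux[0] / area_m2 == pytest.approx(1000.0, rel=1e-12)

    def test_stacked_facet_fully_shades_lower(self):
        tris = np.stack([HORIZ, HORIZ + [0, 0, 30]])
        ts = TriangleSet.from_triangles(tris)
        flux, lit = direct_interception(_scenify(ts), overhead_sun(), 1000.0)
        assert lit[1] and not lit[0]
        assert flux[0] == 0.0 and flux[1] > 0

    def test_oblique_sun_projected_area(self):
        scene = single_facet_scene(HORIZ)
        sun = overhead_sun(zenith=60.0)
        flux, _ = direct_interception(scene, sun, 500.0)
        # horizontal facet: (I/cos z) * cos z * area recovers I * area
        assert flux[0] == pytest.approx(500.0 * scene.areas[0] * 1e-4, rel=1e-12)

    def test_below_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            direct_interception(single_facet_scene(HORIZ), overhead_sun(zenith=95.0), 100.0)

    def test_back_facing_facet_not_sunlit_without_occlusion_test(self):
        scene = single_facet_scene(HORIZ)
        sun = overhead_sun(zenith=60.0, azimuth=90.0)
        _, lit_orientation = direct_interception(scene, sun, 300.0, with_occlusion=False)
        assert lit_orientation[0]  # upward facet faces any above-horizon beam

    def test_monotone_adding_occluder_never_raises_flux(self, rng):
        base = [HORIZ]
        scene = _scenify(TriangleSet.from_triangles(np.stack(base)))
        f0, _ = direct_interception(scene, overhead_sun(30.0), 800.0)
        for _ in range(5):
            base.append(HORIZ + [rng.uniform(-30, 30), rng.uniform(-30, 30), 40])
            scene2 = _scenify(TriangleSet.from_triangles(np.stack(base)))
            f1, _ = direct_interception(scene2, overhead_sun(30.0), 800.0)
            assert f1[0] <= f0[0] + 1e-12


class TestOcclusionOracle:
    def test_production_matches_bruteforce_on_random_scenes(self, rng):
        for _ in range(10):
            n = int(rng.integers(50, 301))
            tris = np.empty((n, 3, 3))
            tris[:, 0] = rng.uniform(0, 150, (n, 3))
            tris[:, 1:] = tris[:, 0:1] + rng.uniform(-20, 20, (n, 2, 3))
            d = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(0.15, 1)])
            d /= np.linalg.norm(d)
            cents = tris.mean(axis=1)
            assert np.array_equal(occluded(cents, d, tris),
                                  naive_ray_occluded(cents, d, tris))

    def test_trimesh_cross_check(self, rng):
        trimesh = pytest.importorskip("trimesh")
        pytest.importorskip("rtree")
        n = 120
        tris = np.empty((n, 3, 3))
        tris[:, 0] = rng.uniform(0, 100, (n, 3))
        tris[:, 1:] = tris[:, 0:1] + rng.uniform(-15, 15, (n, 2, 3))
        d = np.array([0.2, -0.3, 0.93])
        d /= np.linalg.norm(d)
        mesh = trimesh.Trimesh(vertices=tris.reshape(-1, 3),
                               faces=np.arange(3 * n).reshape(-1, 3), process=False)
        cents = tris.mean(axis=1)
        # offset origins slightly along the ray so trimesh skips the self-hit
        hits = mesh.ray.intersects_any(cents + 1e-3 * d, np.tile(d, (n, 1)))
        mine = occluded(cents, d, tris)
        assert (mine == hits).mean() > 0.97  # boundary conventions may differ on seams


class TestDiffuse:
    def test_unobstructed_horizontal_facet_recovers_incident_flux(self):
        scene = single_facet_scene(HORIZ)
        for n_sectors in (16, 46):
            flux = diffuse_interception(scene, SkyModel.build(n_sectors), 400.0)
            dens = flux[0] / (scene.areas[0] * 1e-4)
            assert dens == pytest.approx(400.0, rel=0.02)

    def test_zero_diffuse_zero_flux(self, small_scene):
        assert diffuse_interception(small_scene, SkyModel.build(16), 0.0).sum() == 0.0

    def test_sector_discretization_convergence(self):
        from phytocanopy.synthetic_data import CULTIVARS, generate_plant
        from phytocanopy.geometry import CanopyLayout, assemble_canopy
        plant = generate_plant(CULTIVARS["J2416"], seed=2)
        lay = CanopyLayout(n_rows=3, n_cols=3, focal_rows=1, focal_cols=1)
        scene = assemble_canopy(plant, lay, seed=2, n_segments=4, n_width_strips=1)
        f46 = diffuse_interception(scene, SkyModel.build(46), 300.0)
        f145 = diffuse_interception(scene, SkyModel.build(145), 300.0)
        for pid in range(9):
            m = scene.facets.plant == pid
            assert f46[m].sum() == pytest.approx(f145[m].sum(), rel=0.05)

    def test_sky_weights_normalised(self):
        for n in (16, 46, 145):
            sky = SkyModel.build(n)
            assert sky.n_sectors == n
            assert sky.weights.sum() == pytest.approx(1.0, rel=1e-12)
            assert (sky.directions[:, 2] < 0).all()


class TestHourlyRecords:
    def test_zero_par_hour_zero_records(self, small_scene):
        recs = hourly_records(small_scene, 233, 12, 0.0, 0.0)
        df = records_to_frame(recs)
        assert (df["IPP_umol_leaf_h"] == 0).all()
        assert (df["LA_sun_cm2"] == 0).all()
        # one row per (focal plant, rank)
        assert len(df) == len(small_scene.focal_ids) * 19

    def test_single_horizontal_leaf_closed_form(self):
        # 0.1 m2 horizontal leaf, 1000 umol m-2 s-1 for one hour at noon on
        # the equator near equinox: IPP ~ 1000 * 0.1 * 3600
        tri1 = np.array([[0, 0, 50], [100, 0, 50], [0, 10, 50]], float)
        tri2 = np.array([[100, 0, 50], [100, 10, 50], [0, 10, 50]], float)
        from phytocanopy.geometry import CanopyScene, CanopyLayout
        facets = TriangleSet.from_triangles(np.stack([tri1, tri2]))
        scene = CanopyScene(facets=facets, layout=CanopyLayout(),
                            positions=np.zeros((1, 2)), focal_ids=np.array([0]),
                            wall_height=0.0, plant_specs=[], footprint=(0, 1, 0, 1))
        recs = hourly_records(scene, 81, 12, 600.0, 400.0, sky=SkyModel.build(46),
                              latitude=0.0)
        assert len(recs) == 1
        assert recs[0].LA == pytest.approx(1000.0)
        assert recs[0].IPP == pytest.approx(1000.0 * 0.1 * 3600, rel=2e-3)
        assert recs[0].LA_sun == pytest.approx(1000.0)

    def test_sunlit_area_shrinks_with_sunside_neighbour(self):
        from phytocanopy.synthetic_data import CULTIVARS, generate_plant
        from phytocanopy.geometry import CanopyLayout, assemble_canopy
        plant = generate_plant(CULTIVARS["JNK728"], seed=4)
        lone = assemble_canopy(plant, CanopyLayout(n_rows=3, n_cols=3, focal_rows=1,
                                                   focal_cols=1, plant_density=1.0),
                               seed=4, n_segments=4, n_width_strips=1)
        crowd = assemble_canopy(plant, CanopyLayout(n_rows=3, n_cols=3, focal_rows=1,
                                                    focal_cols=1, plant_density=8.0),
                                seed=4, n_segments=4, n_width_strips=1)
        sun = sun_position(39.93, 233, 12)
        la = {}
        for name, scene in (("lone", lone), ("crowd", crowd)):
            _, lit = direct_interception(scene, sun, 1000.0)
            pid = scene.focal_ids[0]
            m = (scene.facets.plant == pid)
            la_total = scene.facets.areas[m].sum()
            la[name] = scene.facets.areas[m & lit].sum()
            assert la[name] <= la_total
        assert la["crowd"] < la["lone"]


class TestSplit:
    def test_constant_fraction(self):
        direct, diffuse = split_direct_diffuse(1000.0, 30.0, "constant", 0.25)
        assert direct == 750.0 and diffuse == 250.0

    def test_spitters_overcast_is_all_diffuse(self):
        direct, diffuse = split_direct_diffuse(100.0, 30.0, "spitters")
        assert diffuse == pytest.approx(100.0)
        assert direct == pytest.approx(0.0)

    def test_spitters_clear_sky_mostly_direct(self):
        direct, diffuse = split_direct_diffuse(1900.0, 20.0, "spitters")
        assert direct > diffuse


def _scenify(triset):
    from phytocanopy.geometry import CanopyScene, CanopyLayout
    return CanopyScene(facets=triset, layout=CanopyLayout(),
                       positions=np.zeros((1, 2)), focal_ids=np.array([0]),
                       wall_height=0.0, plant_specs=[], footprint=(0, 1, 0, 1))
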