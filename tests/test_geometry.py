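import math

import numpy as np
import pytest

from fetovasc import geometry
from fetovasc.geometry import (GeometryError, InfeasibleInsertionError,
                               PlacentalShapeParams, build_placental_surface,
                               build_placentone, chorionic_area,
                               extract_chorionic_plate, locate_cord_insertion,
                               minor_radius, placental_thickness)


class TestScalarRelations:
    def test_thickness_unit_sphere_identity(self):
        assert placental_thickness(4 * math.pi / 3, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("V,r,expected", [
        (409.1, 8.47, 3 * 409.1 / (4 * math.pi * 8.47 ** 2)),
        (480.0, 9.3, 3 * 480.0 / (4 * math.pi * 9.3 ** 2)),
    ])
    def test_thickness_values(self, V, r, expected):
        got = placental_thickness(V, r)
        assert got == pytest.approx(expected)
        assert 1.3 < got < 1.4  # cm, physiological half-thickness scale

    def test_thickness_invalid(self):
        with pytest.raises(GeometryError):
            placental_thickness(-1, 1)

    @pytest.mark.parametrize("r,E,expected", [
        (5.0, 0.0, 5.0),
        (9.3, 0.49, math.sqrt(9.3 ** 2 * (1 - 0.49 ** 2))),
        (8.47, 0.54, math.sqrt(8.47 ** 2 * (1 - 0.54 ** 2))),
    ])
    def test_minor_radius(self, r, E, expected):
        assert minor_radius(r, E) == pytest.approx(expected)

    def test_minor_radius_invalid_eccentricity(self):
        with pytest.raises(GeometryError):
            minor_radius(5.0, 1.0)

    def test_chorionic_area_half_sphere_limit(self):
        for r in (1.0, 3.7):
            assert chorionic_area(r, r, r) == pytest.approx(2 * math.pi * r ** 2,
                                                            rel=1e-12)

    def test_chorionic_area_monotone(self):
        base = chorionic_area(9.3, 8.1, 1.3)
        assert chorionic_area(9.4, 8.1, 1.3) > base
        assert chorionic_area(9.3, 8.2, 1.3) > base
        assert chorionic_area(9.3, 8.1, 1.4) > base


class TestSpheroidSurface:
    def test_sphere_area_and_volume(self):
        # E=0 and V chosen so all three semi-axes coincide (a true sphere)
        r = 2.0  # cm
        params = PlacentalShapeParams(V=4 * math.pi / 3 * r ** 3, r_maj=r, E=0.0,
                                      CCI=0.0)
        assert params.t_half == pytest.approx(r)
        surf = build_placental_surface(params, target_seed_density=0.5)
        r_mm = r * 10
        assert surf.is_closed
        assert surf.area() == pytest.approx(4 * math.pi * r_mm ** 2, rel=0.01)
        assert surf.volume() == pytest.approx(4 * math.pi / 3 * r_mm ** 3, rel=0.02)

    def test_spheroid_volume_matches_analytic(self, small_shape, coarse_surface):
        a, b, c = coarse_surface.meta["semi_axes"]
        assert coarse_surface.volume() == pytest.approx(
            4 * math.pi / 3 * a * b * c, rel=0.02)

    def test_seed_density_meets_target(self, small_shape):
        surf = build_placental_surface(small_shape, target_seed_density=2.0)
        assert 2.0 <= surf.meta["seed_density"] < 8.0

    def test_density_beyond_budget_raises(self, small_shape):
        with pytest.raises(MemoryError):
            build_placental_surface(small_shape, target_seed_density=1000.0,
                                    max_vertices=100_000)


class TestChorionicPlate:
    def test_plate_area_close_to_target(self, small_shape, coarse_plate):
        target = coarse_plate.meta["target_area_mm2"]
        # within one latitude-row area of the requested chorionic area
        rows = coarse_plate.meta["face_row"]
        areas = coarse_plate.face_areas()
        max_row_area = max(areas[rows == r].sum() for r in np.unique(rows))
        assert abs(coarse_plate.area() - target) <= max_row_area

    def test_plate_single_boundary_loop(self, coarse_plate):
        assert not coarse_plate.is_closed
        loop = coarse_plate.boundary_loop
        assert loop.size > 8
        uniq, counts = coarse_plate.edge_counts()
        assert (counts == 1).sum() == loop.size  # exactly one closed loop

    def test_plate_is_upper_cap(self, coarse_plate):
        # the chorionic plate is the +z side of the placenta
        assert coarse_plate.vertices[:, 2].mean() > 0

    def test_half_area_on_sphere_is_hemisphere(self):
        r = 2.0
        params = PlacentalShapeParams(V=4 * math.pi / 3 * r ** 3, r_maj=r, E=0.0,
                                      CCI=0.0)
        surf = build_placental_surface(params, target_seed_density=0.5)
        patch = extract_chorionic_plate(surf, 2 * math.pi * r ** 2)
        # boundary sits near the equator
        z = patch.vertices[patch.boundary_loop, 2]
        assert np.abs(z).max() < 0.15 * r * 10

    def test_area_larger_than_surface_rejected(self, coarse_surface):
        with pytest.raises(GeometryError):
            extract_chorionic_plate(coarse_surface, 1e9)


class TestCordInsertion:
    def test_central_insertion_near_centroid(self, coarse_plate):
        idx = locate_cord_insertion(coarse_plate, 0.0, 9.3, 0.0,
                                    np.random.default_rng(0))
        c = coarse_plate.centroid
        d = np.linalg.norm(coarse_plate.vertices[idx, :2] - c[:2])
        assert d < 15.0  # within a couple of mesh edges of the centroid

    def test_target_distance_matched(self, coarse_plate):
        # CCI=0.36, r_maj=9.3 cm: the insertion should land ~33.5 mm out
        idx = locate_cord_insertion(coarse_plate, 0.36, 9.3, 20.0,
                                    np.random.default_rng(1))
        c = coarse_plate.centroid
        d = np.linalg.norm(coarse_plate.vertices[idx, :2] - c[:2])
        assert d == pytest.approx(33.48, abs=12.0)

    def test_margin_constraint_respected(self, coarse_plate):
        from scipy.spatial import cKDTree
        idx = locate_cord_insertion(coarse_plate, 0.9, 9.3, 20.0,
                                    np.random.default_rng(2))
        btree = cKDTree(coarse_plate.vertices[coarse_plate.boundary_loop])
        dist, _ = btree.query(coarse_plate.vertices[idx])
        assert dist >= 20.0

    def test_infeasible_margin_raises(self, coarse_plate):
        with pytest.raises(InfeasibleInsertionError):
            locate_cord_insertion(coarse_plate, 0.0, 9.3, 1e4,
                                  np.random.default_rng(3))


class TestPlacentone:
    @pytest.mark.parametrize("V,th,n_p,expected", [
        (480.0, 24.0, 65, math.sqrt(480e3 / (24 * 65))),
        (292.5, 18.0, 42, math.sqrt(292.5e3 / (18 * 42))),
    ])
    def test_cross_section(self, V, th, n_p, expected):
        dom = build_placentone(V, th, n_p, 1.88, 5.6)
        assert dom.X_p == pytest.approx(expected)
        assert dom.X_p == dom.Y_p

    def test_mesh_watertight_and_volume(self, small_placentone):
        dom = small_placentone
        assert dom.surface.is_closed
        assert dom.surface.volume() == pytest.approx(dom.volume, rel=1e-6)

    def test_cavity_apex_boundary(self, small_placentone):
        dom = small_placentone
        apex = np.array([0.0, 0.0, -dom.t_half + dom.CC_h])
        eps = np.array([0.0, 0.0, 1e-6])
        assert bool(dom.cavity_test(apex - eps))
        assert not bool(dom.cavity_test(apex + eps))

    def test_cavity_sits_on_basal_face(self, small_placentone):
        dom = small_placentone
        assert bool(dom.cavity_test([0.0, 0.0, -dom.t_half + 0.1]))
        assert not bool(dom.cavity_test([0.0, 0.0, dom.t_half - 0.1]))

    def test_oversize_cavity_rejected(self):
        with pytest.raises(GeometryError):
            build_placentone(390.0, 24.0, 65, 20.0, 5.6)
        with pytest.raises(GeometryError):
            build_placentone(390.0, 24.0, 65, 1.88, 30.0)

    def test_mesh_export_import_roundtrip(self, small_placentone, tmp_path):
        path = tmp_path / "placentone.stl"
        small_placentone.surface.export(path)
        back = geometry.TriangulatedSurface.load(path)
        assert back.is_closed
        assert back.volume() == pytest.approx(small_placentone.volume, rel=1e-5)
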