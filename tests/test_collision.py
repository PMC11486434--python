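import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetovasc import collision, geometry
from fetovasc.collision import (CollisionError, SegmentCylinder,
                                candidates_collision_free,
                                finite_cylinder_collision, line_line_distance,
                                point_in_mesh, roi_filter, venous_clearance_ok)
from fetovasc.geometry import TriangulatedSurface, _latlong_spheroid
from fetovasc.trees import TreeBuilder

from conftest import random_tree


def exact_ray_parity(surface, points, direction=(0.12, 0.34, 0.93)):
    """Brute-force Möller–Trumbore crossing-parity oracle."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    v = surface.vertices
    tri = v[surface.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    out = []
    for p in np.atleast_2d(points):
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        mask = np.abs(a) > 1e-12
        f = np.zeros_like(a)
        f[mask] = 1.0 / a[mask]
        s = p - tri[:, 0]
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        w = f * (q @ d)
        t = f * np.einsum("ij,ij->i", q, e2)
        hit = mask & (u >= 0) & (w >= 0) & (u + w <= 1) & (t > 1e-9)
        out.append(hit.sum() % 2 == 1)
    return np.array(out)


@pytest.fixture(scope="module")
def unit_cube():
    return geometry._box_mesh(1.0, 1.0, 1.0, 0.5)


@pytest.fixture(scope="module")
def sphere_mesh():
    v, f, _ = _latlong_spheroid(10.0, 10.0, 10.0, 20)
    return TriangulatedSurface(v, f)


class TestPointInMesh:
    def test_unit_cube(self, unit_cube):
        assert point_in_mesh(unit_cube, np.array([0.0, 0.0, 0.0]))
        assert not point_in_mesh(unit_cube, np.array([2.0, 0.0, 0.0]))

    def test_sphere_radial_probes(self, sphere_mesh):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        assert point_in_mesh(sphere_mesh, dirs * 9.0).all()
        assert not point_in_mesh(sphere_mesh, dirs * 11.0).any()

    def test_agrees_with_exact_ray_cast(self, sphere_mesh):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-12, 12, size=(400, 3))
        # skip points within a voxel of the surface where the grid quantizes
        r = np.linalg.norm(pts, axis=1)
        pts = pts[np.abs(r - 10.0) > 0.6]
        ours = point_in_mesh(sphere_mesh, pts)
        oracle = exact_ray_parity(sphere_mesh, pts)
        assert np.array_equal(ours, oracle)

    def test_parity_invariant_under_ray_direction(self, unit_cube):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, size=(200, 3))
        near_face = (np.abs(np.abs(pts) - 0.5) < 0.05).any(axis=1)
        pts = pts[~near_face]
        a = exact_ray_parity(unit_cube, pts, (0.1, 0.2, 0.97))
        b = exact_ray_parity(unit_cube, pts, (0.9, -0.3, 0.2))
        assert np.array_equal(a, b)
        assert np.array_equal(point_in_mesh(unit_cube, pts), a)

    def test_open_mesh_rejected(self, coarse_plate):
        with pytest.raises(CollisionError):
            collision.VoxelizedMesh(coarse_plate)


class TestRoiFilter:
    def _candidate(self):
        return SegmentCylinder(np.zeros(3), np.array([10.0, 0, 0]), 1.0)

    def test_empty_tree(self):
        b = TreeBuilder()
        b.add_node((0, 0, 0))
        assert roi_filter(b.build(), self._candidate()).size == 0

    def test_parent_at_start_included(self):
        # a segment ending at the candidate start lies l/2 < 3l/5 from midpoint
        b = TreeBuilder()
        r = b.add_node((-5.0, 0, 0))
        b.add_node((0.0, 0, 0), parent=r, diameter=1.0)
        assert roi_filter(b.build(), self._candidate()).tolist() == [1]

    def test_distant_segment_excluded(self):
        b = TreeBuilder()
        r = b.add_node((0, 50.0, 0))
        b.add_node((5, 50.0, 0), parent=r, diameter=1.0)
        assert roi_filter(b.build(), self._candidate()).size == 0


class TestLineDistance:
    def test_examples(self):
        x = SegmentCylinder((0, 0, 0), (1, 0, 0), 1.0)
        assert line_line_distance(x, SegmentCylinder((5, 0, 0), (9, 0, 0), 1.0)) == 0
        par = SegmentCylinder((0, 2.0, 0), (1, 2.0, 0), 1.0)
        assert line_line_distance(x, par) == pytest.approx(2.0)
        skew = SegmentCylinder((0, 1.0, 1.0), (0, 2.0, 1.0), 1.0)
        assert line_line_distance(x, skew) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 5
        if np.linalg.norm(pts[1] - pts[0]) < 1e-3 or \
           np.linalg.norm(pts[3] - pts[2]) < 1e-3:
            return
        a = SegmentCylinder(pts[0], pts[1], 1.0)
        b = SegmentCylinder(pts[2], pts[3], 1.0)
        d0 = line_line_distance(a, b)
        assert line_line_distance(b, a) == pytest.approx(d0, abs=1e-9)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3)
        a2 = SegmentCylinder(q @ pts[0] + t, q @ pts[1] + t, 1.0)
        b2 = SegmentCylinder(q @ pts[2] + t, q @ pts[3] + t, 1.0)
        assert line_line_distance(a2, b2) == pytest.approx(d0, abs=1e-8)


class TestVenousClearance:
    def test_threshold_arithmetic(self):
        a = SegmentCylinder((0, 0, 0), (10, 0, 0), 1.0)
        ok = SegmentCylinder((0, 3.6, 0), (10, 3.6, 0), 1.0)
        bad = SegmentCylinder((0, 3.4, 0), (10, 3.4, 0), 1.0)
        assert venous_clearance_ok(a, ok)        # 3.6 > (7/4)·2
        assert not venous_clearance_ok(a, bad)   # 3.4 < 3.5
        touching = SegmentCylinder((0, 0, 0), (0, 10, 0), 0.5)
        assert not venous_clearance_ok(a, touching)  # DL = 0


class TestFiniteCylinders:
    def test_collinear_overlap(self):
        a = SegmentCylinder((0, 0, 0), (10, 0, 0), 1.0)
        b = SegmentCylinder((5, 0, 0), (15, 0, 0), 1.0)
        assert finite_cylinder_collision(a, b)

    def test_perpendicular_clearance(self):
        a = SegmentCylinder((0, 0, 0), (10, 0, 0), 1.0)
        b = SegmentCylinder((5, -5, 1.2), (5, 5, 1.2), 1.0)  # gap 0.2 > 0
        assert not finite_cylinder_collision(a, b)
        c = SegmentCylinder((5, -5, 0.8), (5, 5, 0.8), 1.0)  # overlap
        assert finite_cylinder_collision(a, c)

    def test_shared_node_contact(self):
        a = SegmentCylinder((0, 0, 0), (10, 0, 0), 1.0)
        b = SegmentCylinder((10, 0, 0), (20, 5, 0), 0.8)
        assert finite_cylinder_collision(a, b)

    def test_degenerate_rejected(self):
        with pytest.raises(CollisionError):
            SegmentCylinder((1, 1, 1), (1, 1, 1), 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_capsule_oracle(self, seed):
        """Axis-distance oracle decides clear-cut pairs; GJK must agree."""
        rng = np.random.default_rng(seed)
        checked = 0
        for _ in range(250):
            p = rng.uniform(-5, 5, size=(4, 3))
            d1, d2 = rng.uniform(0.3, 2.0, size=2)
            if np.linalg.norm(p[1] - p[0]) < 0.5 or np.linalg.norm(p[3] - p[2]) < 0.5:
                continue
            a = SegmentCylinder(p[0], p[1], d1)
            b = SegmentCylinder(p[2], p[3], d2)
            dist, interior = collision.segment_distance_matrix(
                p[0][None], p[1][None], p[2][None], p[3][None])
            contact = (d1 + d2) / 2
            # only assert where the polygonal approximation cannot flip the answer
            if dist[0, 0] > contact * 1.05:
                assert not finite_cylinder_collision(a, b)
                checked += 1
            elif dist[0, 0] < contact * 0.95 and interior[0, 0]:
                assert finite_cylinder_collision(a, b)
                checked += 1
        assert checked > 50


class TestPipeline:
    def test_empty_segment_set_passes(self):
        ok = candidates_collision_free(np.zeros((1, 3)), np.ones((1, 3)) * 5,
                                       np.array([1.0]), np.empty((0, 3)),
                                       np.empty((0, 3)), np.empty(0))
        assert ok.tolist() == [True]

    def test_clearance_fast_accepts(self):
        # far apart: clearance holds, no finite test needed
        ok = candidates_collision_free(
            np.array([[0.0, 0, 0]]), np.array([[10.0, 0, 0]]), np.array([1.0]),
            np.array([[0.0, 8.0, 0]]), np.array([[10.0, 8.0, 0]]), np.array([1.0]))
        assert ok.tolist() == [True]

    def test_overlapping_rejected_and_exempt_respected(self):
        seg_s = np.array([[0.0, 0.5, 0]])
        seg_e = np.array([[10.0, 0.5, 0]])
        seg_d = np.array([1.0])
        c_s = np.array([[0.0, 0, 0]])
        c_e = np.array([[10.0, 0, 0]])
        ok = candidates_collision_free(c_s, c_e, np.array([1.0]),
                                       seg_s, seg_e, seg_d)
        assert ok.tolist() == [False]
        exempt = np.ones((1, 1), dtype=bool)
        ok = candidates_collision_free(c_s, c_e, np.array([1.0]),
                                       seg_s, seg_e, seg_d, exempt=exempt)
        assert ok.tolist() == [True]

    def test_audit_detects_and_clears(self):
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        n1 = b.add_node((10, 0, 0), parent=r, diameter=2.0)
        b.add_node((10, 10, 0), parent=n1, diameter=1.5)  # adjacent: exempt
        assert collision.audit_tree_clearances(b.build()) == 0
        # a fourth, non-adjacent segment slicing through the first
        b2 = TreeBuilder()
        r = b2.add_node((0, 0, 0))
        n1 = b2.add_node((10, 0, 0), parent=r, diameter=2.0)
        n2 = b2.add_node((10, 10, 0), parent=n1, diameter=1.5)
        b2.add_node((5, -5, 0), parent=n2, diameter=1.0)  # crosses segment 1
        assert collision.audit_tree_clearances(b2.build()) >= 1
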