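import numpy as np
import pytest

from fetovasc import collision, trees, villous
from fetovasc.villous import (VillousGrowthParams, branch_plane_normal,
                              default_stem, grow_villous_tree,
                              sample_sphere_candidates, score_candidates_villous)


@pytest.fixture(scope="module")
def small_tree(small_placentone):
    """A bg_v=6 villous tree shared across structural tests."""
    params = VillousGrowthParams(bg_v=6)
    rng = np.random.default_rng(21)
    stem = default_stem(small_placentone, params, rng)
    return grow_villous_tree(small_placentone, stem, params, rng)


class TestPlaneNormal:
    def test_xy_plane(self):
        n = branch_plane_normal((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert abs(n[2]) == pytest.approx(1.0)
        assert n[:2] == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_unit_norm_and_orthogonality(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            c, p, g = rng.normal(size=(3, 3))
            if np.linalg.norm(np.cross(p - c, g - c)) < 1e-6:
                continue
            n = branch_plane_normal(c, p, g)
            assert np.linalg.norm(n) == pytest.approx(1.0)
            assert abs(n @ (p - c)) < 1e-12 * max(1, np.linalg.norm(p - c))
            assert abs(n @ (g - c)) < 1e-12 * max(1, np.linalg.norm(g - c))

    def test_collinear_fallback_orthogonal(self):
        n = branch_plane_normal((0, 0, 0), (1, 0, 0), (2, 0, 0), rng=1)
        assert np.linalg.norm(n) == pytest.approx(1.0)
        assert abs(n[0]) < 1e-9  # orthogonal to the parent direction


class TestSphereSampling:
    def test_radius_exact(self):
        pts = sample_sphere_candidates((1.0, 2.0, 3.0), 5.0, 300, rng=0)
        r = np.linalg.norm(pts - np.array([1.0, 2.0, 3.0]), axis=1)
        assert np.allclose(r, 5.0, atol=1e-9)

    def test_mean_approaches_center(self):
        pts = sample_sphere_candidates(np.zeros(3), 1.0, 4000, rng=1)
        # CLT: per-axis sd of the mean is 1/sqrt(3n)
        assert np.linalg.norm(pts.mean(axis=0)) < 3.0 / np.sqrt(4000)

    def test_halves_populated(self):
        rng = np.random.default_rng(2)
        pts = sample_sphere_candidates(np.zeros(3), 1.0, 200, rng=3)
        for _ in range(10):
            n = rng.normal(size=3)
            side = pts @ n > 0
            assert 0 < side.sum() < 200

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            sample_sphere_candidates(np.zeros(3), -1.0, 10)


class TestScoring:
    def test_on_plane_candidate_has_zero_d1(self):
        cs = score_candidates_villous(np.array([[1.0, 1.0, 0.0]]),
                                      (0, 0, 1.0), np.zeros(3),
                                      np.array([[0, 0, -5.0]]), 0.7, 0.3)
        assert cs.D1[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_free_plane_distance(self):
        cands = np.array([[0, 0, 2.0], [0, 0, -2.0]])
        cs = score_candidates_villous(cands, (0, 0, 1.0), np.zeros(3),
                                      np.array([[50.0, 0, 0]]), 0.7, 0.3)
        assert cs.D1[0] == pytest.approx(cs.D1[1]) == pytest.approx(2.0)

    def test_cf1_zero_ranks_by_basal_distance(self):
        cands = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 0.0]])
        basal = np.array([[0, 0, -10.0]])
        cs = score_candidates_villous(cands, (1.0, 0, 0), np.zeros(3),
                                      basal, 0.0, 1.0)
        assert cs.order.tolist() == [1, 2, 0]  # closest to basal first


class TestGrowth:
    def test_generation_cap_one(self, small_placentone):
        params = VillousGrowthParams(bg_v=1)
        rng = np.random.default_rng(5)
        tree = grow_villous_tree(small_placentone,
                                 default_stem(small_placentone, params, rng),
                                 params, rng)
        assert 1 <= tree.n_segments <= 3  # stem plus at most two daughters

    def test_root_outside_domain_rejected(self, small_placentone):
        params = VillousGrowthParams()
        stem = (np.array([0.0, 0, 50.0]), np.array([0.0, 0, 48.0]), 0.7)
        with pytest.raises(ValueError):
            grow_villous_tree(small_placentone, stem, params, 0)

    def test_structure_and_containment(self, small_tree, small_placentone):
        tree = small_tree
        tree.validate()
        assert (tree.segment_generation[tree.segments] <= 6).all()
        pts = tree.node_coords[1:]  # root sits on the +z face boundary
        assert small_placentone.contains(pts, margin=-1e-9).all()
        assert not small_placentone.cavity_test(pts).any()

    def test_containment_against_mesh_oracle(self, small_tree, small_placentone):
        # voxel-parity inside test agrees with the analytic box on node probes
        inside_mesh = collision.point_in_mesh(small_placentone.surface,
                                              small_tree.node_coords[2:])
        assert inside_mesh.all()

    def test_diameters_non_increasing(self, small_tree):
        t = small_tree
        for s in t.segments:
            p = t.parent_index[s]
            if t.parent_index[p] != trees.ROOT:
                assert t.segment_diameters[s] <= t.segment_diameters[p] + 1e-12

    def test_daughters_split_by_branching_plane(self, small_placentone):
        params = VillousGrowthParams(bg_v=4)
        rng = np.random.default_rng(8)
        tree = grow_villous_tree(small_placentone,
                                 default_stem(small_placentone, params, rng),
                                 params, rng)
        par = tree.parent_index
        counts = tree.child_counts()
        checked = 0
        for node in range(tree.n_nodes):
            kids = np.flatnonzero(par == node)
            if kids.size != 2 or par[node] == trees.ROOT:
                continue
            gp = par[node]
            if par[gp] == trees.ROOT:
                continue
            n_v = branch_plane_normal(tree.node_coords[node],
                                      tree.node_coords[gp],
                                      tree.node_coords[par[gp]])
            s1 = np.sign(n_v @ (tree.node_coords[kids[0]] - tree.node_coords[node]))
            s2 = np.sign(n_v @ (tree.node_coords[kids[1]] - tree.node_coords[node]))
            assert s1 * s2 < 0
            checked += 1
        assert checked > 3
        del counts

    def test_no_clearance_violations_post_hoc(self, small_tree):
        assert collision.audit_tree_clearances(small_tree) == 0

    def test_seed_reproducibility(self, small_placentone):
        params = VillousGrowthParams(bg_v=4)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            stem = default_stem(small_placentone, params, rng)
            out.append(grow_villous_tree(small_placentone, stem, params, rng))
        np.testing.assert_array_equal(out[0].node_coords, out[1].node_coords)
        np.testing.assert_array_equal(out[0].parent_index, out[1].parent_index)

    def test_cf2_pulls_towards_basal_plate(self, small_placentone):
        """Raising the basal-attraction weight lowers mean node-basal distance."""
        from scipy.spatial import cKDTree
        basal = cKDTree(small_placentone.basal_vertices())
        means = {}
        for cf1, cf2 in ((0.9, 0.1), (0.1, 0.9)):
            dists = []
            for seed in range(4):
                params = VillousGrowthParams(bg_v=5, cf1=cf1, cf2=cf2)
                rng = np.random.default_rng(1000 + seed)
                tree = grow_villous_tree(
                    small_placentone,
                    default_stem(small_placentone, params, rng), params, rng)
                d, _ = basal.query(tree.node_coords[2:])
                dists.append(d.mean())
            means[cf2] = np.mean(dists)
        assert means[0.9] < means[0.1]


class TestFullVasculature:
    def test_stage_composition_without_villous(self, small_shape):
        tree = villous.grow_full_vasculature(small_shape, None,
                                             VillousGrowthParams(bg_v=2),
                                             rng_seed=2, seed_density=0.5,
                                             include_villous=False)
        labels = set(tree.segment_label[tree.segments])
        assert labels == {"umbilical", "chorionic", "stem"}

    def test_merged_forest(self, small_shape):
        tree = villous.grow_full_vasculature(small_shape, None,
                                             VillousGrowthParams(bg_v=2),
                                             rng_seed=2, seed_density=0.5)
        tree.validate()
        labels = set(tree.segment_label[tree.segments])
        assert "villous" in labels
        assert tree.roots.size == 2  # one root per umbilical artery
        assert tree.meta["n_stems"] >= 1
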