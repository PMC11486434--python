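import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetovasc import trees
from fetovasc.trees import (TreeBuilder, TreeError, branching_angle_3d,
                            length_to_diameter, morphometry_summary,
                            murray_daughter_diameters, strahler_orders,
                            strahler_ratios, read_swc, write_swc)

from conftest import random_tree


def perfect_binary_tree(depth: int, d0: float = 4.0, diameter_ratio: float = 0.8,
                        length0: float = 10.0, length_ratio: float = 0.8):
    """Complete bifurcating tree; level-g segments have d0·r^g, l0·r^g."""
    builder = TreeBuilder()
    root = builder.add_node((0.0, 0.0, 0.0))
    level = [(root, np.array([0.0, 0.0, 0.0]))]
    for g in range(depth):
        nxt = []
        d = d0 * diameter_ratio ** g
        length = length0 * length_ratio ** g
        for k, (parent, pos) in enumerate(level):
            for s in (1, -1):
                u = np.array([s * 0.6, 0.3 * math.sin(2.1 * k + s), -0.7])
                u /= np.linalg.norm(u)
                off = length * u  # exact per-level segment length
                node = builder.add_node(pos + off, parent=parent, diameter=d,
                                        generation=g, label="villous")
                nxt.append((node, pos + off))
        level = nxt
    return builder.build()


class TestElementaryOps:
    def test_length_to_diameter(self):
        assert length_to_diameter(10, 1) == 10
        assert length_to_diameter(0, 2) == 0
        # the in-silico literature mean ratio is recovered for any diameter
        for d in (0.03, 0.7, 4.6):
            assert length_to_diameter(8.46 * d, d) == pytest.approx(8.46)
        with pytest.raises(TreeError):
            length_to_diameter(1, 0)

    @pytest.mark.parametrize("cj,cg,expected", [
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
    ])
    def test_branching_angle(self, cj, cg, expected):
        assert branching_angle_3d(cj, (0, 0, 0), cg) == pytest.approx(expected)

    def test_branching_angle_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cj, ci, cg = rng.normal(size=(3, 3))
            base = branching_angle_3d(cj, ci, cg)
            assert branching_angle_3d(cg, ci, cj) == pytest.approx(base)
            # random rotation + translation
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            t = rng.normal(size=3)
            assert branching_angle_3d(q @ cj + t, q @ ci + t,
                                      q @ cg + t) == pytest.approx(base)

    def test_branching_angle_zero_arm(self):
        with pytest.raises(TreeError):
            branching_angle_3d((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize("d0,k,a,d1,d2", [
        (1.0, 3.0, 1.0, 2 ** (-1 / 3), 2 ** (-1 / 3)),
        (4.6, 3.2, 1.0, 4.6 * 2 ** (-1 / 3.2), 4.6 * 2 ** (-1 / 3.2)),
        (1.0, 3.0, 2.0, 2 * 9 ** (-1 / 3), 9 ** (-1 / 3)),
    ])
    def test_murray_examples(self, d0, k, a, d1, d2):
        got = murray_daughter_diameters(d0, k, a)
        assert got == pytest.approx((d1, d2), rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(d0=st.floats(0.01, 10), k=st.floats(1.0, 4.0), a=st.floats(0.2, 5.0))
    def test_murray_conservation(self, d0, k, a):
        d1, d2 = murray_daughter_diameters(d0, k, a)
        assert d1 ** k + d2 ** k == pytest.approx(d0 ** k, rel=1e-12)
        assert 0 < d1 < d0 and 0 < d2 < d0
        assert d1 == pytest.approx(a * d2, rel=1e-12)

    def test_murray_invalid(self):
        with pytest.raises(TreeError):
            murray_daughter_diameters(-1, 3, 1)


def brute_force_strahler(tree) -> np.ndarray:
    """Independent post-order recursion for segment Strahler orders."""
    children = {i: [] for i in range(tree.n_nodes)}
    for s in tree.segments:
        children[int(tree.parent_index[s])].append(int(s))
    orders = np.zeros(tree.n_nodes, dtype=int)

    def visit(node):
        kids = children[node]
        if not kids:
            return 1
        kid_orders = [visit(k) for k in kids]
        for k, o in zip(kids, kid_orders):
            orders[k] = o
        if len(kid_orders) == 1:
            return kid_orders[0]
        return max(kid_orders) + (1 if kid_orders[0] == kid_orders[1] else 0)

    for root in tree.roots:
        for k in children[int(root)]:
            orders[k] = visit(k)
    return orders


class TestStrahler:
    def test_single_segment(self):
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        b.add_node((0, 0, 1), parent=r, diameter=1.0)
        assert strahler_orders(b.build()).tolist() == [0, 1]

    def test_monopodial_chain_all_order_one(self):
        b = TreeBuilder()
        prev = b.add_node((0, 0, 0))
        for i in range(3):
            prev = b.add_node((0, 0, i + 1.0), parent=prev, diameter=1.0 - 0.1 * i)
        orders = strahler_orders(b.build())
        assert orders[1:].tolist() == [1, 1, 1]

    def test_trunk_plus_two_bifurcation_levels(self):
        # a root trunk segment feeding 2 then 4 segments
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        trunk = b.add_node((0, 0, 1), parent=r, diameter=4.0)
        mids = [b.add_node((s, 0, 2), parent=trunk, diameter=3.0)
                for s in (1, -1)]
        for m in mids:
            for s in (1, -1):
                b.add_node(np.asarray(b.coords[m]) + (0.5 * s, 0.5, 1),
                           parent=m, diameter=2.0)
        orders = strahler_orders(b.build())
        counts = np.bincount(orders[1:])
        assert counts[1] == 4 and counts[2] == 2 and counts[3] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(5, 200)))
        assert np.array_equal(strahler_orders(tree), brute_force_strahler(tree))

    def test_branching_ratio_two_on_perfect_binary(self):
        tree = perfect_binary_tree(5)
        branching, _, _ = strahler_ratios(tree)
        assert branching == pytest.approx(2.0, abs=1e-9)

    def test_geometric_diameter_and_length_ratios_recovered(self):
        r_d, r_l = 1.6, 1.3
        tree = perfect_binary_tree(5, diameter_ratio=1 / r_d, length_ratio=1 / r_l)
        # exact geometric sequences per level; orders equal depth levels here
        _, dia, length = strahler_ratios(tree)
        assert dia == pytest.approx(r_d, rel=1e-9)
        assert length == pytest.approx(r_l, rel=1e-9)

    def test_single_order_tree_raises(self):
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        b.add_node((0, 0, 1), parent=r, diameter=1.0)
        with pytest.raises(TreeError):
            strahler_ratios(b.build())


class TestMorphometry:
    def test_single_segment_summary(self):
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        b.add_node((0, 0, 10.0), parent=r, diameter=1.0, label="stem")
        s = morphometry_summary(b.build(), domain_volume=1e6)
        assert s.mean_path_length_mm == pytest.approx(10.0)
        assert s.mean_ltd == pytest.approx(10.0)
        assert s.segment_count == 1
        assert s.mean_terminal_length_mm == pytest.approx(10.0)

    def test_symmetric_murray_diameter_ratio(self):
        tree = perfect_binary_tree(3, d0=1.0, diameter_ratio=2 ** (-1 / 3))
        s = morphometry_summary(tree, domain_volume=1e6)
        assert s.mean_diameter_ratio == pytest.approx(2 ** (-1 / 3), rel=1e-9)
        assert s.sd_diameter_ratio == pytest.approx(0.0, abs=1e-12)

    def test_invalid_domain_volume(self):
        tree = perfect_binary_tree(2)
        with pytest.raises(TreeError):
            morphometry_summary(tree, domain_volume=0)

    def test_validate_rejects_growing_diameters(self):
        b = TreeBuilder()
        r = b.add_node((0, 0, 0))
        n = b.add_node((0, 0, 1), parent=r, diameter=1.0)
        b.add_node((0, 0, 2), parent=n, diameter=2.0)
        with pytest.raises(TreeError):
            b.build().validate()


class TestSerialization:
    def test_swc_roundtrip(self, tmp_path):
        tree = perfect_binary_tree(3)
        path = tmp_path / "tree.swc"
        write_swc(tree, path)
        back = read_swc(path)
        assert back.n_nodes == tree.n_nodes
        np.testing.assert_allclose(back.node_coords, tree.node_coords, atol=1e-5)
        np.testing.assert_array_equal(back.parent_index, tree.parent_index)
        segs = tree.segments
        np.testing.assert_allclose(back.segment_diameters[segs],
                                   tree.segment_diameters[segs], atol=1e-5)
        assert list(back.segment_label[segs]) == list(tree.segment_label[segs])

    def test_csv_export(self, tmp_path):
        tree = perfect_binary_tree(2)
        trees.write_csv(tree, tmp_path / "t.csv", tmp_path / "t.json")
        lines = (tmp_path / "t.csv").read_text().strip().splitlines()
        assert len(lines) == tree.n_nodes + 1
        assert lines[0].startswith("child_id,parent_id")
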