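"""Morphometric operations against independent brute-force oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, MultiPoint
from shapely.strtree import STRtree

from sacmorph.morphometry import (
    branch_level_histogram,
    classify_hypertrophic,
    count_branch_points,
    count_self_crossings,
    field_area_convex_hull,
    sholl_analysis,
    soma_area,
    total_dendrite_length,
)
from sacmorph.synthetic import ArborParams, gen_arbor
from sacmorph.types import NeuriteTree

from conftest import make_tree


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def sholl_oracle(tree: NeuriteTree, radii: np.ndarray, n_samples: int = 400):
    """Dense-sampling crossing counter, independent of the analytic route."""
    soma = tree.soma_xyz[:2]
    t = np.linspace(0.0, 1.0, n_samples)
    counts = np.zeros(len(radii), dtype=int)
    for pi, ci in tree.edges():
        p0 = tree.xyz[pi, :2] - soma
        p1 = tree.xyz[ci, :2] - soma
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        dist = np.linalg.norm(pts, axis=1)
        for k, r in enumerate(radii):
            sign = np.sign(dist - r)
            counts[k] += int(np.sum(np.abs(np.diff(sign[sign != 0])) > 1))
    return counts


def crossing_oracle(tree: NeuriteTree, z_tolerance: float = 1.0) -> int:
    """Self-crossing count via shapely predicates + z interpolation."""
    e = tree.edges()
    segs = [LineString([tree.xyz[a, :2], tree.xyz[b, :2]]) for a, b in e]
    stree = STRtree(segs)
    ii, jj = stree.query(segs, predicate="crosses")
    n = 0
    for a, b in zip(ii, jj):
        if a >= b:
            continue
        pt = segs[a].intersection(segs[b])
        if pt.geom_type != "Point":
            continue
        za = _z_at(tree, e[a], pt.x, pt.y)
        zb = _z_at(tree, e[b], pt.x, pt.y)
        if abs(za - zb) <= z_tolerance:
            n += 1
    return n


def _z_at(tree, edge, x, y):
    p0, p1 = tree.xyz[edge[0]], tree.xyz[edge[1]]
    seg = p1[:2] - p0[:2]
    t = np.dot([x - p0[0], y - p0[1]], seg) / np.dot(seg, seg)
    return p0[2] + t * (p1[2] - p0[2])


def hull_area_triplet_oracle(points: np.ndarray) -> float:
    """Exhaustive hull: a point is a vertex iff not strictly inside any
    triangle of other points; area by angular sort of the vertices."""
    n = len(points)
    keep = []
    for i in range(n):
        inside = False
        for a in range(n):
            for b in range(a + 1, n):
                for c in range(b + 1, n):
                    if i in (a, b, c):
                        continue
                    if _in_triangle(points[i], points[a], points[b], points[c]):
                        inside = True
                        break
                if inside:
                    break
            if inside:
                break
        if not inside:
            keep.append(points[i])
    hull = np.array(keep)
    ctr = hull.mean(axis=0)
    ang = np.arctan2(hull[:, 1] - ctr[1], hull[:, 0] - ctr[0])
    hull = hull[np.argsort(ang)]
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def _in_triangle(p, a, b, c):
    def cross(u, v, w):
        return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
    return (d1 > 0 and d2 > 0 and d3 > 0) or (d1 < 0 and d2 < 0 and d3 < 0)


# ---------------------------------------------------------------------------
# length, branch points, levels
# ---------------------------------------------------------------------------

class TestLengthAndBranching:
    def test_chain_of_unit_edges(self, chain_tree):
        assert total_dendrite_length(chain_tree) == pytest.approx(5.0)

    def test_soma_only(self):
        t = make_tree([(1, -1, 0, 0, 0, 4.0)])
        assert total_dendrite_length(t) == 0.0

    def test_generated_tree_matches_edge_sum_oracle(self):
        tree = gen_arbor(ArborParams(seed=21))
        expected = 0.0
        for i in range(len(tree)):
            p = tree.parent[i]
            if p != -1:
                expected += float(
                    np.linalg.norm(tree.xyz[i] - tree.xyz[tree.index_of(p)])
                )
        assert total_dendrite_length(tree) == pytest.approx(expected, abs=1e-9)

    def test_single_bifurcation_counts_once(self, bifurcation_tree):
        assert count_branch_points(bifurcation_tree) == 1

    def test_soma_trunks_do_not_count(self, four_trunk_tree):
        assert count_branch_points(four_trunk_tree) == 0

    def test_trifurcation_counts_once(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 10, 0, 0, 0.3),
            (3, 2, 20, 5, 0, 0.3),
            (4, 2, 20, 0, 0, 0.3),
            (5, 2, 20, -5, 0, 0.3),
        ])
        assert count_branch_points(t) == 1

    def test_levels_single_bifurcating_trunk(self, bifurcation_tree):
        assert branch_level_histogram(bifurcation_tree) == {1: 1, 2: 2}

    def test_levels_four_trunks(self, four_trunk_tree):
        assert branch_level_histogram(four_trunk_tree) == {1: 4}

    def test_levels_full_binary_depth3(self):
        # one trunk, each branch bifurcates twice more: levels 1, 2, 3
        nodes = [(1, -1, 0.0, 0.0, 0, 4.0), (2, 1, 10.0, 0.0, 0, 0.3)]
        nid = 3
        frontier = [(2, 10.0, 0.0)]
        for depth in range(2):
            nxt = []
            for parent, x, y in frontier:
                for dy in (5.0, -5.0):
                    nodes.append((nid, parent, x + 10.0, y + dy / (depth + 1), 0, 0.3))
                    nxt.append((nid, x + 10.0, y + dy / (depth + 1)))
                    nid += 1
            frontier = nxt
        t = make_tree(nodes)
        assert branch_level_histogram(t) == {1: 1, 2: 2, 3: 4}

    def test_histogram_counts_sum_to_branch_count(self):
        tree = gen_arbor(ArborParams(seed=2))
        hist = branch_level_histogram(tree)
        # binary tree: branches = 2 * branch points + n_primary
        children = tree.children_map()
        root = tree.root_index
        n_branches = sum(
            1 for k, ch in children.items()
            for _ in ch
            if True
        )
        # every junction child starts one branch
        n_expected = sum(
            len(ch) for k, ch in children.items()
            if k == root or len(ch) >= 2
        )
        assert sum(hist.values()) == n_expected


# ---------------------------------------------------------------------------
# Sholl
# ---------------------------------------------------------------------------

class TestSholl:
    def test_straight_trunk(self):
        t = make_tree([(1, -1, 0, 0, 0, 4.0), (2, 1, 100, 0, 0, 0.3)])
        radii, raw, norm = sholl_analysis(t, step=1.0)
        assert len(radii) == 100
        assert np.all(raw[:99] == 1)
        assert raw[99] == 0  # tip sits exactly on the r=100 circle
        assert np.allclose(norm[:9], 1.0)

    def test_trunk_then_symmetric_bifurcation(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 50, 0, 0, 0.3),
            (3, 2, 100, 30, 0, 0.3),
            (4, 2, 100, -30, 0, 0.3),
        ])
        radii, raw, _ = sholl_analysis(t, step=1.0)
        assert np.all(raw[radii < 50] == 1)
        sel = (radii > 50) & (radii < 100)
        assert np.all(raw[sel] == 2)

    def test_generated_trees_match_sampling_oracle(self):
        for seed in (0, 1, 2):
            tree = gen_arbor(ArborParams(seed=seed))
            radii, raw, _ = sholl_analysis(tree, step=1.0)
            assert np.array_equal(raw, sholl_oracle(tree, radii))

    def test_rotation_invariance(self):
        tree = gen_arbor(ArborParams(seed=4))
        _, raw, _ = sholl_analysis(tree)
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        xyz = tree.xyz.copy()
        xyz[:, :2] = xyz[:, :2] @ rot.T
        rotated = NeuriteTree(ids=tree.ids, parent=tree.parent, xyz=xyz,
                              radius=tree.radius, kind=tree.kind)
        _, raw_rot, _ = sholl_analysis(rotated)
        assert np.array_equal(raw, raw_rot)

    def test_degenerate_tree_raises(self):
        t = make_tree([(1, -1, 0, 0, 0, 4.0)])
        with pytest.raises(ValueError):
            sholl_analysis(t)


# ---------------------------------------------------------------------------
# hull, crossings, caliber, soma
# ---------------------------------------------------------------------------

class TestFieldArea:
    def test_square(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 100, 0, 0, 0.3),
            (3, 1, 100, 100, 0, 0.3),
            (4, 1, 0, 100, 0, 0.3),
        ])
        assert field_area_convex_hull(t) == pytest.approx(10000.0)

    def test_right_triangle(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 30, 0, 0, 0.3),
            (3, 1, 0, 40, 0, 0.3),
        ])
        assert field_area_convex_hull(t) == pytest.approx(600.0)

    def test_random_cloud_matches_triplet_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, size=(25, 2))
        nodes = [(1, -1, pts[0, 0], pts[0, 1], 0, 4.0)]
        nodes += [(i + 2, 1, pts[i + 1, 0], pts[i + 1, 1], 0, 0.3)
                  for i in range(24)]
        t = make_tree(nodes)
        assert field_area_convex_hull(t) == pytest.approx(
            hull_area_triplet_oracle(pts), abs=1e-6
        )

    def test_collinear_raises(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 10, 0, 0, 0.3),
            (3, 2, 20, 0, 0, 0.3),
        ])
        with pytest.raises(ValueError):
            field_area_convex_hull(t)


class TestSelfCrossings:
    def _x_tree(self, dz: float):
        return make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 10, -1, 0, 0.3),
            (3, 2, 30, -1, 0, 0.3),  # horizontal-ish edge
            (4, 1, 20, -10, dz, 0.3),
            (5, 4, 20, 10, dz, 0.3),  # vertical edge crossing it
        ])

    def test_crossing_at_equal_z(self):
        assert count_self_crossings(self._x_tree(0.0)) == 1

    def test_z_separated_not_counted(self):
        assert count_self_crossings(self._x_tree(5.0), z_tolerance=1.0) == 0

    def test_siblings_at_branch_point_excluded(self, bifurcation_tree):
        assert count_self_crossings(bifurcation_tree) == 0

    def test_generated_trees_match_shapely_oracle(self):
        for seed in (0, 1, 2):
            tree = gen_arbor(ArborParams(seed=seed))
            assert count_self_crossings(tree) == crossing_oracle(tree)

    def test_invariant_under_edge_order(self):
        tree = gen_arbor(ArborParams(seed=6))
        perm = np.random.default_rng(0).permutation(np.arange(1, len(tree)))
        order = np.concatenate([[0], perm])
        shuffled = NeuriteTree(
            ids=tree.ids[order], parent=tree.parent[order],
            xyz=tree.xyz[order], radius=tree.radius[order],
            kind=tree.kind[order],
        )
        assert count_self_crossings(shuffled) == count_self_crossings(tree)


class TestHypertrophic:
    def test_thin_cell_not_flagged(self, four_trunk_tree):
        flagged, ids = classify_hypertrophic(four_trunk_tree)
        assert flagged is False and ids == []

    def test_thick_trunk_flagged(self):
        t = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (2, 1, 50, 0, 0, 0.7),   # 1.4 um caliber trunk
            (3, 1, 0, 50, 0, 0.3),
        ])
        flagged, ids = classify_hypertrophic(t)
        assert flagged is True and ids == [2]

    def test_exactly_threshold_not_flagged(self):
        t = make_tree([(1, -1, 0, 0, 0, 4.0), (2, 1, 50, 0, 0, 0.5)])
        flagged, _ = classify_hypertrophic(t, caliber_threshold=1.0)
        assert flagged is False


class TestSomaArea:
    def test_unit_square(self):
        assert soma_area([[0, 0], [1, 0], [1, 1], [0, 1]]) == pytest.approx(1.0)

    def test_regular_hexagon(self):
        r = 5.0
        ang = np.deg2rad(np.arange(0, 360, 60))
        poly = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        assert soma_area(poly) == pytest.approx(3 * math.sqrt(3) / 2 * r**2, abs=1e-4)

    def test_orientation_invariance(self):
        poly = [[0, 0], [2, 0], [2, 1], [0, 1]]
        assert soma_area(poly) == soma_area(poly[::-1])

    def test_self_intersecting_raises(self):
        with pytest.raises(ValueError):
            soma_area([[0, 0], [1, 1], [1, 0], [0, 1]])


class TestStructuralInvariances:
    def test_interior_node_insertion_is_noop(self, bifurcation_tree):
        t = bifurcation_tree
        # split edge 1->2 by inserting a pass-through node at its midpoint
        split = make_tree([
            (1, -1, 0, 0, 0, 4.0),
            (9, 1, 5, 0, 0, 0.3),
            (2, 9, 10, 0, 0, 0.3),
            (3, 2, 20, 5, 0, 0.3),
            (4, 2, 20, -5, 0, 0.3),
        ])
        assert total_dendrite_length(split) == pytest.approx(total_dendrite_length(t))
        assert count_branch_points(split) == count_branch_points(t)
        assert branch_level_histogram(split) == branch_level_histogram(t)
        assert field_area_convex_hull(split) == pytest.approx(
            field_area_convex_hull(t)
        )
        _, raw_a, _ = sholl_analysis(t)
        _, raw_b, _ = sholl_analysis(split)
        assert np.array_equal(raw_a, raw_b)

    def test_translation_invariance(self):
        tree = gen_arbor(ArborParams(seed=8))
        moved = NeuriteTree(
            ids=tree.ids, parent=tree.parent,
            xyz=tree.xyz + np.array([123.0, -45.0, 0.0]),
            radius=tree.radius, kind=tree.kind,
        )
        assert total_dendrite_length(moved) == pytest.approx(
            total_dendrite_length(tree)
        )
        assert field_area_convex_hull(moved) == pytest.approx(
            field_area_convex_hull(tree)
        )
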