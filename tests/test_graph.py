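"""Skeletonization, graph extraction, pruning, diameters, rooting."""

import numpy as np
import pytest

import retmorph as rm
from retmorph.graph import build_graph, prune_spurs, root_components, skeletonize


def line_mask(shape, p0, p1, width):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    p = np.stack([rr, cc], -1).astype(float)
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0, 1)
    d = np.hypot(*(p - (a + t[..., None] * ab)).transpose(2, 0, 1))
    return d <= width / 2


class TestSkeletonize:
    def test_idempotent_on_one_pixel_diagonal(self):
        m = np.zeros((30, 30), bool)
        idx = np.arange(5, 25)
        m[idx, idx] = True
        sk = skeletonize(rm.RasterMask(m))
        assert np.array_equal(sk, m)
        assert np.array_equal(skeletonize(rm.RasterMask(sk)), sk)

    def test_skeleton_subset_of_foreground(self):
        m = line_mask((60, 60), (10, 10), (50, 45), 7)
        sk = skeletonize(rm.RasterMask(m))
        assert not (sk & ~m).any()

    def test_filled_rectangle_thins_to_midline_path(self):
        m = np.zeros((21, 45), bool)
        m[7:14, 7:38] = True  # 7 rows x 31 cols
        sk = skeletonize(rm.RasterMask(m))
        rows, cols = np.nonzero(sk)
        # medial axis of a 7x31 rectangle is (mostly) its middle row
        assert 25 <= sk.sum() <= 31
        assert np.abs(rows - 10).max() <= 1

    def test_empty_mask_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            sk = skeletonize(rm.RasterMask(np.zeros((10, 10), bool)))
        assert not sk.any()

    def test_plus_sign_has_one_junction_cluster(self):
        m = line_mask((61, 61), (30, 5), (30, 55), 7) | line_mask((61, 61), (5, 30), (55, 30), 7)
        g = build_graph(skeletonize(rm.RasterMask(m)))
        junctions = [n for n in g.nodes.values() if n.landmark == "junction"]
        assert len(junctions) == 1
        assert g.degree(junctions[0].id) == 4


class TestBuildGraph:
    def test_straight_line_two_endpoints_one_edge(self):
        m = line_mask((40, 40), (8, 8), (32, 30), 5)
        g = build_graph(skeletonize(rm.RasterMask(m)))
        assert len(g.edges) == 1
        assert sorted(n.landmark for n in g.nodes.values()) == ["endpoint", "endpoint"]

    def test_y_shape_three_endpoints_one_junction(self):
        m = (
            line_mask((80, 80), (70, 40), (40, 40), 5)
            | line_mask((80, 80), (40, 40), (12, 18), 5)
            | line_mask((80, 80), (40, 40), (12, 62), 5)
        )
        g = build_graph(skeletonize(rm.RasterMask(m)))
        marks = sorted(n.landmark for n in g.nodes.values())
        assert marks == ["endpoint", "endpoint", "endpoint", "junction"]
        assert len(g.edges) == 3

    def test_pixel_conservation(self, arcade_mask):
        sk = skeletonize(arcade_mask)
        g = build_graph(sk)
        n_cluster = sum(n.n_pixels for n in g.nodes.values())
        n_interior = sum(len(e.interior) for e in g.edges.values())
        assert n_cluster + n_interior == int(sk.sum())

    def test_edge_paths_end_at_node_positions(self, arcade_mask):
        g = build_graph(skeletonize(arcade_mask))
        for e in g.edges.values():
            u, v = e.nodes
            assert np.allclose(e.path[0], g.nodes[u].position)
            assert np.allclose(e.path[-1], g.nodes[v].position)
            # arc length is at least the chord between the nodes
            chord = np.hypot(*(g.nodes[u].position - g.nodes[v].position))
            assert e.length >= chord - 1e-9


class TestPruneSpurs:
    def _y_with_spur(self):
        m = (
            line_mask((90, 90), (80, 45), (45, 45), 7)
            | line_mask((90, 90), (45, 45), (12, 20), 7)
            | line_mask((90, 90), (45, 45), (12, 70), 7)
            | line_mask((90, 90), (45, 45), (41, 52), 3)  # short spur
        )
        mask = rm.RasterMask(m)
        g = build_graph(skeletonize(mask))
        return rm.estimate_diameters(mask, g)

    def test_short_spur_removed_and_edges_kept(self):
        g = prune_spurs(self._y_with_spur(), min_length=10)
        assert len(g.edges) == 3
        assert all(n.landmark in ("endpoint", "junction") for n in g.nodes.values())

    def test_zero_threshold_is_identity(self):
        g0 = self._y_with_spur()
        g = prune_spurs(g0, min_length=0)
        assert len(g.edges) == len(g0.edges)
        assert len(g.nodes) == len(g0.nodes)

    def test_fixpoint_no_short_terminal_edges_remain(self, arcade_mask):
        mask = arcade_mask
        g = rm.estimate_diameters(mask, build_graph(skeletonize(mask)))
        for thr in (4, 8, 15):
            p = prune_spurs(g, min_length=thr)
            for e in p.edges.values():
                u, v = e.nodes
                du, dv = p.degree(u), p.degree(v)
                if (du == 1 and dv >= 3) or (dv == 1 and du >= 3):
                    assert e.length >= thr

    def test_edge_count_monotone_in_threshold(self, arcade_mask):
        g = rm.estimate_diameters(arcade_mask, build_graph(skeletonize(arcade_mask)))
        counts = [len(prune_spurs(g, min_length=t).edges) for t in (0, 3, 6, 12, 25)]
        assert counts == sorted(counts, reverse=True)

    def test_isolated_segment_never_pruned(self):
        m = line_mask((40, 40), (10, 10), (14, 14), 3)
        mask = rm.RasterMask(m)
        g = rm.estimate_diameters(mask, build_graph(skeletonize(mask)))
        assert len(prune_spurs(g, min_length=50).edges) == len(g.edges)


class TestDiameters:
    def test_width_one_line_bounded_by_rasterization(self):
        m = np.zeros((30, 30), bool)
        m[15, 5:25] = True
        mask = rm.RasterMask(m)
        g = rm.estimate_diameters(mask, build_graph(skeletonize(mask)))
        e = next(iter(g.edges.values()))
        assert 1.0 <= e.mean_diameter <= 2.0

    def test_planned_tree_diameters_recovered(self, disc):
        from retmorph.synthetic import Segment, TreeSpec

        segs = [
            Segment(0, None, (350.0, 405.0), (0.30, 0.954), 60.0, 10.0),
            Segment(1, 0, (368.0, 462.2), (0.62, 0.784), 55.0, 8.0),
            Segment(2, 0, (368.0, 462.2), (-0.22, 0.975), 55.0, 6.0),
        ]
        from retmorph.synthetic import PlannedJunction

        j = PlannedJunction((368.0, 462.2), 0, (1, 2), 52.0, (0.8, 0.6))
        spec = TreeSpec("artery", (350.0, 405.0), (0.30, 0.954), segs, [j], disc)
        mask = rm.render_tree(spec, 700, 700)
        g = rm.extract_graph(mask, disc)
        measured = sorted(e.mean_diameter for e in g.edges.values())
        for got, want in zip(measured, [6.0, 8.0, 10.0]):
            assert abs(got - want) <= 0.10 * want


class TestRootComponents:
    def test_path_rooted_at_end_near_disc(self):
        m = line_mask((200, 200), (100, 60), (100, 160), 5)
        mask = rm.RasterMask(m)
        disc = rm.DiscGeometry((100.0, 50.0), 20.0)
        g = root_components(build_graph(skeletonize(mask)), disc)
        root = g.nodes[g.roots[0]]
        assert root.position[1] < 80  # the end nearest the disc
        for e in g.edges.values():
            assert e.nodes[0] == root.id or g.nodes[e.nodes[0]].landmark != "root"

    def test_synthetic_root_matches_planned_root(self, arcade_pair, arcade_mask, disc):
        g = rm.extract_graph(arcade_mask, disc)
        planned = [np.asarray(s.root_point) for s in arcade_pair]
        for root in g.roots:
            pos = g.nodes[root].position
            assert min(np.hypot(*(pos - p)) for p in planned) <= 2.0

    def test_far_components_dropped(self):
        m = line_mask((300, 300), (20, 20), (40, 40), 5) | line_mask(
            (300, 300), (150, 150), (170, 170), 5
        )
        mask = rm.RasterMask(m)
        disc = rm.DiscGeometry((160.0, 160.0), 30.0)
        g = root_components(build_graph(skeletonize(mask)), disc)
        assert len(g.roots) == 1  # far top-left path is debris (> 3 DD away)

    def test_error_when_nothing_rootable(self):
        m = line_mask((300, 300), (10, 10), (30, 30), 5)
        mask = rm.RasterMask(m)
        disc = rm.DiscGeometry((280.0, 280.0), 20.0)
        with pytest.raises(ValueError, match="no rooted vasculature"):
            root_components(build_graph(skeletonize(mask)), disc)

    def test_rooted_graph_is_acyclic_from_roots(self, arcade_graph):
        g = arcade_graph
        for root in g.roots:
            seen = set()
            stack = [root]
            while stack:
                nid = stack.pop()
                for e in g.out_edges(nid):
                    assert e.id not in seen, "directed cycle"
                    seen.add(e.id)
                    stack.append(e.nodes[1])
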