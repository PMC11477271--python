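"""Skeleton graphs versus a brute-force pixel-walk oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nquant import (
    CellSpec,
    ImagingParams,
    build_skeleton_graph,
    generate_neuron_scene,
    skeletonize_mask,
    spine_metrics,
)

SQRT2 = np.sqrt(2.0)


def pixel_graph(skeleton):
    """Independent oracle: the full pixel-level weighted graph."""
    g = nx.Graph()
    pix = list(map(tuple, np.argwhere(skeleton)))
    pset = set(pix)
    g.add_nodes_from(pix)
    for (r, c) in pix:
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if (dr, dc) == (0, 0):
                continue
            q = (r + dr, c + dc)
            if q in pset:
                g.add_edge((r, c), q, weight=SQRT2 if dr and dc else 1.0)
    return g


def line_skeleton():
    sk = np.zeros((10, 20), bool)
    sk[5, 3:13] = True
    return sk


def t_skeleton():
    sk = np.zeros((40, 40), bool)
    sk[10, 5:25] = True     # stem, 20 px
    sk[10:21, 15] = True    # bar, 11 px sharing the junction pixel
    return sk


def plus_skeleton():
    sk = np.zeros((30, 30), bool)
    sk[15, 5:26] = True
    sk[5:26, 15] = True
    return sk


class TestSkeletonize:
    def test_rectangle_thins_to_straight_line(self):
        mask = np.zeros((20, 70), bool)
        mask[8:11, 10:60] = True
        skel = skeletonize_mask(mask)
        assert skel.sum() == pytest.approx(48, abs=2)
        assert (skel & ~mask).sum() == 0
        graph = build_skeleton_graph(skel)
        assert len(graph.endpoints) == 2
        assert len(graph.junctions) == 0

    def test_single_pixel_survives(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert skeletonize_mask(mask).sum() == 1

    def test_disk_skeleton_much_smaller_than_disk(self):
        from nquant.synthetic import disk_mask
        disk = disk_mask((60, 60), (30, 30), 20)
        skel = skeletonize_mask(disk)
        assert skel.sum() < 0.05 * disk.sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize_mask(np.zeros((8, 8), bool))


class TestSkeletonGraph:
    def test_straight_line_single_edge_of_length_nine(self):
        graph = build_skeleton_graph(line_skeleton())
        assert len(graph.endpoints) == 2
        assert len(graph.junctions) == 0
        assert len(graph.edges) == 1
        assert graph.edges[0].length == pytest.approx(9.0)

    def test_t_shape_topology(self):
        graph = build_skeleton_graph(t_skeleton())
        assert len(graph.junctions) == 1
        assert len(graph.endpoints) == 3
        assert len(graph.edges) == 3

    def test_plus_shape_topology(self):
        graph = build_skeleton_graph(plus_skeleton())
        assert len(graph.junctions) == 1
        assert len(graph.endpoints) == 4
        assert len(graph.edges) == 4

    @pytest.mark.parametrize("maker", [line_skeleton, t_skeleton,
                                       plus_skeleton])
    def test_edge_lengths_match_pixel_walk_oracle(self, maker):
        """Each traced edge length equals the brute-force shortest-path
        distance between its terminal pixels over the raw pixel graph."""
        skel = maker()
        graph = build_skeleton_graph(skel)
        oracle = pixel_graph(skel)
        for e in graph.edges:
            d = nx.dijkstra_path_length(oracle, e.path[0], e.path[-1],
                                        weight="weight")
            assert e.length == pytest.approx(d)

    @pytest.mark.parametrize("maker", [line_skeleton, t_skeleton,
                                       plus_skeleton])
    def test_tree_euler_relation(self, maker):
        graph = build_skeleton_graph(maker())
        assert len(graph.edges) == len(graph.nodes) - 1

    def test_edge_length_bounds_euclidean_distance(self):
        for maker in (line_skeleton, t_skeleton, plus_skeleton):
            graph = build_skeleton_graph(maker())
            for e in graph.edges:
                p0, p1 = np.array(e.path[0]), np.array(e.path[-1])
                assert e.length >= np.hypot(*(p1 - p0)) - 1e-9
                assert e.length > 0

    def test_empty_skeleton_raises(self):
        with pytest.raises(ValueError):
            build_skeleton_graph(np.zeros((6, 6), bool))

    def test_main_axis_and_sides_partition_edges(self):
        graph = build_skeleton_graph(t_skeleton())
        assert set(graph.main_axis) | set(graph.side_branches) == set(
            range(len(graph.edges)))
        assert not set(graph.main_axis) & set(graph.side_branches)


class TestSpineMetrics:
    def test_line_has_no_branches(self):
        graph = build_skeleton_graph(line_skeleton())
        m = spine_metrics(graph, 2, 20)
        assert m.branch_count == 0
        assert m.n_branches == 0
        assert m.mean_branch_length == 0.0

    def test_t_side_branch_counted_once(self):
        sk = np.zeros((30, 40), bool)
        sk[10, 2:32] = True     # long stem
        sk[11:16, 16] = True    # side branch, 5 px below the stem
        graph = build_skeleton_graph(sk)
        m = spine_metrics(graph, 2, 20)
        assert m.branch_count == 1
        assert m.mean_branch_length == pytest.approx(5.0)
        assert m.relative_count == pytest.approx(1 / graph.main_axis_length)

    def test_short_spur_excluded_by_min_length(self):
        sk = np.zeros((20, 40), bool)
        sk[10, 2:32] = True
        sk[11, 16] = True       # 1-px spur
        graph = build_skeleton_graph(sk)
        assert spine_metrics(graph, 2, 20).branch_count == 0

    def test_long_daughter_neurite_excluded_by_max_length(self):
        sk = np.zeros((60, 80), bool)
        sk[10, 2:72] = True     # stem, 70 px
        sk[11:36, 40] = True    # 25-px daughter branch
        graph = build_skeleton_graph(sk)
        assert spine_metrics(graph, 2, 20).branch_count == 0
        assert spine_metrics(graph, 2, 30).branch_count == 1

    def test_single_node_skeleton_has_no_main_axis(self):
        sk = np.zeros((5, 5), bool)
        sk[2, 2] = True
        graph = build_skeleton_graph(sk)
        with pytest.raises(ValueError, match="main axis"):
            spine_metrics(graph)

    def test_adding_one_spine_increases_count_by_one(self):
        """On the noise-free raster, each extra generated spine adds one
        side branch to the skeleton graph."""
        params = ImagingParams((200, 260), seed=2).noise_free()
        counts = []
        for spine_cols in ([100], [100, 140], [100, 140, 180]):
            spines = tuple(((100, c), 90, 8, 2.0) for c in spine_cols)
            spec = CellSpec((100, 40), 10,
                            neurites=[([(100, 50), (100, 230)], 3.0)],
                            spines=spines)
            scene = generate_neuron_scene([spec], params)
            neurite_mask = scene.truth.neurite_masks[0]
            graph = build_skeleton_graph(skeletonize_mask(neurite_mask))
            counts.append(spine_metrics(graph, 2, 30).branch_count)
        assert counts == [1, 2, 3]
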