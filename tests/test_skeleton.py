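import numpy as np
import pytest
from skimage.draw import circle_perimeter
from skimage.measure import euler_number, label

from vasculomorph.imaging_io import BinaryMask, PolygonROI
from vasculomorph.skeleton import (
    ENDPOINT,
    JUNCTION,
    SLAB,
    Skeleton,
    SkeletonBranch,
    SkeletonGraph,
    analyze_collaterals,
    analyze_mask,
    build_skeleton_graph,
    classify_pixels,
    measure_branches,
    path_step_length,
    summarize_skeleton,
    thin_mask,
)
from vasculomorph.synthetic import generate_grid, random_branch_path

from conftest import random_blob_mask


def skel_from(coords, shape=(32, 32)):
    data = np.zeros(shape, dtype=bool)
    for y, x in coords:
        data[y, x] = True
    return Skeleton(data)


def line_skeleton(n=11, shape=(16, 32)):
    return skel_from([(8, 4 + i) for i in range(n)], shape)


def plus_skeleton():
    coords = [(10, 6 + i) for i in range(9)] + [(6 + i, 10) for i in range(9)]
    return skel_from(set(coords), (24, 24))


class TestThinning:
    def test_idempotent_on_line(self):
        sk = line_skeleton()
        out = thin_mask(BinaryMask(sk.data))
        assert np.array_equal(out.data, sk.data)

    def test_bar_centerline(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:13, 5:55] = True  # 5-px-wide bar
        sk = thin_mask(BinaryMask(mask))
        ys, xs = np.nonzero(sk.data)
        assert set(ys) == {10}
        assert abs(xs.min() - 5) <= 2 and abs(xs.max() - 54) <= 2

    def test_annulus_keeps_hole(self):
        yy, xx = np.mgrid[0:60, 0:60]
        r = np.hypot(yy - 30, xx - 30)
        mask = (r > 8) & (r < 20)
        sk = thin_mask(BinaryMask(mask))
        # Euler-characteristic oracle: components - holes preserved
        assert euler_number(mask, connectivity=2) == euler_number(sk.data, connectivity=2)
        assert label(sk.data, connectivity=2).max() == 1

    def test_one_px_wide(self):
        for seed in range(10):
            sk = thin_mask(BinaryMask(random_blob_mask(seed)))
            d = sk.data
            assert not (d[:-1, :-1] & d[1:, :-1] & d[:-1, 1:] & d[1:, 1:]).any()

    def test_empty_mask(self):
        sk = thin_mask(BinaryMask(np.zeros((5, 5), dtype=bool)))
        assert sk.pixel_count == 0


class TestClassify:
    def test_straight_line(self):
        tags = classify_pixels(line_skeleton(11))
        assert (tags == ENDPOINT).sum() == 2
        assert (tags == SLAB).sum() == 9
        assert (tags == JUNCTION).sum() == 0

    def test_plus_sign(self):
        # the center has 4 neighbors; its 4 arm neighbors also exceed 2
        # neighbors through diagonal adjacency, so the junction *pixels*
        # form one 8-connected cluster = one junction vertex
        sk = plus_skeleton()
        tags = classify_pixels(sk)
        assert (tags == ENDPOINT).sum() == 4
        assert label(tags == JUNCTION, connectivity=2).max() == 1
        g = build_skeleton_graph(sk, tags)
        assert len(g.junction_vertices) == 1
        assert len(g.endpoint_vertices) == 4
        assert len(g.branches) == 4

    def test_isolated_pixel(self):
        tags = classify_pixels(skel_from([(3, 3)], (8, 8)))
        assert (tags == ENDPOINT).sum() == 1

    def test_partition_property(self):
        for seed in range(20):
            sk = thin_mask(BinaryMask(random_blob_mask(seed)))
            tags = classify_pixels(sk)
            total = (tags > 0).sum()
            assert total == sk.pixel_count
            parts = sum(int((tags == t).sum()) for t in (ENDPOINT, SLAB, JUNCTION))
            assert parts == sk.pixel_count


class TestGraph:
    def test_y_shape(self):
        coords = [(10, 2 + i) for i in range(8)]  # stem west
        coords += [(10 - i, 10 + i) for i in range(1, 8)]  # NE arm
        coords += [(10 + i, 10 + i) for i in range(1, 8)]  # SE arm
        sk = skel_from(coords + [(10, 10)], (32, 32))
        g = build_skeleton_graph(sk)
        assert len(g.branches) == 3
        assert len(g.junction_vertices) == 1
        assert len(g.endpoint_vertices) == 3
        assert g.vertex_degree(g.junction_vertices[0].vertex_id) == 3

    def test_straight_line_single_branch(self):
        g = build_skeleton_graph(line_skeleton())
        assert len(g.branches) == 1
        assert len(g.junction_vertices) == 0

    def test_discrete_circle_is_cycle(self):
        data = np.zeros((64, 64), dtype=bool)
        rr, cc = circle_perimeter(32, 32, 20)
        data[rr, cc] = True
        g = build_skeleton_graph(Skeleton(data))
        assert len(g.branches) == 1
        assert g.branches[0].is_cycle
        assert len(g.endpoint_vertices) == 0 and len(g.junction_vertices) == 0

    def test_branch_paths_cover_skeleton(self):
        for seed in range(5):
            sk = thin_mask(BinaryMask(random_blob_mask(seed)))
            g = build_skeleton_graph(sk, merge_junction_px=0)
            covered = set()
            for b in g.branches:
                covered.update(map(tuple, b.path))
            for v in g.vertices:
                covered.update(v.pixels)
            ys, xs = np.nonzero(sk.data)
            assert covered == set(zip(ys.tolist(), xs.tolist()))

    def test_spur_suppression(self):
        # T-shape with one 2-px stub: pruned when min_branch_px is set
        coords = [(10, 2 + i) for i in range(17)]  # horizontal bar
        coords += [(10 - i, 10) for i in range(1, 3)]  # short stub up
        sk = skel_from(coords, (32, 32))
        g_raw = build_skeleton_graph(sk)
        assert len(g_raw.branches) == 3
        g = build_skeleton_graph(sk, min_branch_px=5)
        assert len(g.branches) == 2
        assert len(g.endpoint_vertices) == 2

    def test_prune_cycles_other_modes_rejected(self):
        with pytest.raises(NotImplementedError):
            build_skeleton_graph(line_skeleton(), prune_cycles="shortest")


def single_branch_graph(path, px=1.0):
    return SkeletonGraph([], [SkeletonBranch(0, None, None, np.asarray(path))], px)


class TestMeasures:
    def test_horizontal_branch(self):
        path = [(5, x) for x in range(11)]  # 10 steps
        m = measure_branches(single_branch_graph(path))[0]
        assert m.length_um == pytest.approx(10.0)
        assert m.euclidean_um == pytest.approx(10.0)
        assert m.tortuosity == pytest.approx(1.0)

    def test_l_path(self):
        path = [(10, x) for x in range(6)] + [(10 - i, 5) for i in range(1, 6)]
        m = measure_branches(single_branch_graph(path))[0]
        assert m.length_um == pytest.approx(10.0)
        assert m.euclidean_um == pytest.approx(np.sqrt(50))
        assert m.tortuosity == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_diagonal_branch(self):
        path = [(i, i) for i in range(11)]
        m = measure_branches(single_branch_graph(path))[0]
        assert m.length_um == pytest.approx(10 * np.sqrt(2))
        assert m.tortuosity == pytest.approx(1.0)

    def test_pixel_size_scaling(self):
        path = [(0, x) for x in range(5)]
        m = measure_branches(single_branch_graph(path, px=2.5))[0]
        assert m.length_um == pytest.approx(10.0)

    def test_cycle_tortuosity_undefined(self):
        path = [(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]
        m = measure_branches(single_branch_graph(path))[0]
        assert np.isnan(m.tortuosity)

    def test_random_paths_tortuosity_at_least_one(self, rng):
        for _ in range(200):
            path = random_branch_path(rng)
            if len(path) < 2:
                continue
            m = measure_branches(single_branch_graph(path))[0]
            if m.euclidean_um > 0:
                assert m.tortuosity >= 1.0 - 1e-12


class TestSummary:
    def test_empty(self):
        g = build_skeleton_graph(Skeleton(np.zeros((5, 5), dtype=bool)))
        s = summarize_skeleton(g)
        assert s.branch_count == 0 and s.junction_count == 0 and s.endpoint_count == 0

    def test_depth2_tree_counts(self, tree_depth2_mask):
        _, g, meas, s = analyze_mask(tree_depth2_mask)
        assert s.branch_count == 7
        assert s.junction_count == 3
        assert s.endpoint_count == 5
        assert s.triple_point_count == 3
        assert s.avg_branch_length_um <= s.max_branch_length_um

    def test_max_branch_is_known(self, tree_depth2, tree_depth2_mask):
        _, gt = tree_depth2
        _, _, meas, s = analyze_mask(tree_depth2_mask)
        expect_max = max(b.step_length_px for b in gt.branches)
        assert s.max_branch_length_um == pytest.approx(expect_max, rel=0.05)


class TestCollaterals:
    def test_grid_collaterals(self):
        mask, gt = generate_grid(3, 3, spacing_px=40, width_px=3)
        _, g, meas, _ = analyze_mask(mask)
        # ROI around the middle horizontal row: covers 3 of its 4 segments
        roi = PolygonROI([[-1, 70], [130, 70], [130, 90], [-1, 90]])
        rep = analyze_collaterals(g, meas, roi)
        assert rep.count == 3
        assert rep.mean_tortuosity == pytest.approx(1.0, abs=0.02)
        for length in rep.lengths_um:
            assert length == pytest.approx(40, abs=4)

    def test_empty_roi(self, tree_depth2_mask):
        _, g, meas, _ = analyze_mask(tree_depth2_mask)
        roi = PolygonROI([[5000, 5000], [5010, 5000], [5005, 5010]])
        rep = analyze_collaterals(g, meas, roi)
        assert rep.count == 0 and rep.mean_length_um == 0.0


class TestPipelineRecovery:
    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_tree_recovery(self, depth):
        from vasculomorph.synthetic import TreeSpec, generate_tree

        _, gt = generate_tree(TreeSpec(depth=depth, seed=3))
        _, _, meas, s = analyze_mask(BinaryMask(gt.stroke_mask))
        assert s.branch_count == gt.branch_count
        assert s.junction_count == gt.junction_count
        assert s.endpoint_count == gt.endpoint_count
        got = np.sort([m.length_um for m in meas])
        want = np.sort(gt.branch_step_lengths_px())
        assert np.all(np.abs(got - want) / want <= 0.05)


def test_path_step_length_mixed():
    path = [(0, 0), (0, 1), (1, 2), (2, 2)]
    assert path_step_length(np.asarray(path)) == pytest.approx(2 + np.sqrt(2))
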