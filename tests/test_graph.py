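import numpy as np
import pytest
from scipy import ndimage as ndi

from hiervess.graph import (
    bulge_size,
    extract_graph,
    prune_graph,
    read_graph,
    skeletonize,
    write_graph,
)
from hiervess.phantom import PhantomSpec, generate_tree, branch_recall


def _tube_mask(shape, a, b, r):
    idx = np.indices(shape).reshape(3, -1).T + 0.5
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip((idx - a) @ ab / (ab @ ab), 0, 1)
    d = np.linalg.norm(idx - (a + t[:, None] * ab), axis=1)
    return (d <= r).reshape(shape)


class TestSkeletonize:
    def test_straight_tube_gives_single_path_two_endpoints(self):
        m = _tube_mask((48, 16, 16), (4, 8, 8), (44, 8, 8), 3.0)
        sk = skeletonize(m)
        kernel = np.ones((3, 3, 3), np.int8)
        kernel[1, 1, 1] = 0
        ncount = ndi.convolve(sk.astype(np.int8), kernel, mode="constant")
        ncount[~sk] = 0
        assert (ncount == 1).sum() == 2  # exactly two endpoints
        assert not (ncount >= 3).any()  # no branch voxels
        _, ncomp = ndi.label(sk, structure=np.ones((3, 3, 3), bool))
        assert ncomp == 1

    def test_solid_sphere_collapses_to_point_like_skeleton(self):
        shape = (21, 21, 21)
        x, y, z = np.indices(shape)
        m = (x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 64
        sk = skeletonize(m)
        _, ncomp = ndi.label(sk, structure=np.ones((3, 3, 3), bool))
        assert ncomp == 1 and sk.sum() <= 20
        ext = np.ptp(np.argwhere(sk), axis=0)
        assert ext.max() <= 5  # compact blob at the sphere center

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((5, 5, 5), bool)).any()


class TestExtractGraph:
    def test_straight_tube_graph(self):
        m = _tube_mask((48, 16, 16), (4, 8, 8), (44, 8, 8), 3.0)
        vg = extract_graph(skeletonize(m), m, (1.0, 1.0, 1.0))
        assert vg.n_nodes == 2 and vg.n_segments == 1
        seg = vg.segments[0]
        assert seg.length == pytest.approx(40.0, rel=0.12)  # ends retract ~r
        assert abs(seg.avg_diameter / 2 - 3.0) <= 1.0  # radius within one voxel

    def test_y_junction_has_three_endpoints_one_branch(self):
        m = (
            _tube_mask((64, 64, 24), (6, 32, 12), (32, 32, 12), 3.0)
            | _tube_mask((64, 64, 24), (32, 32, 12), (56, 50, 12), 3.0)
            | _tube_mask((64, 64, 24), (32, 32, 12), (56, 14, 12), 3.0)
        )
        vg = extract_graph(skeletonize(m), m, (1.0, 1.0, 1.0))
        kinds = sorted(n.kind for n in vg.nodes)
        assert vg.n_segments == 3
        assert kinds.count("endpoint") == 3 and kinds.count("branch") == 1

    def test_disjoint_tubes_give_two_components(self):
        m = _tube_mask((40, 30, 12), (4, 6, 6), (36, 6, 6), 2.5) | _tube_mask(
            (40, 30, 12), (4, 22, 6), (36, 22, 6), 2.5
        )
        vg = extract_graph(skeletonize(m), m, (1.0, 1.0, 1.0))
        import networkx as nx

        assert nx.number_connected_components(vg.g) == 2

    def test_anisotropic_spacing_scales_lengths(self):
        m = _tube_mask((48, 16, 16), (4, 8, 8), (44, 8, 8), 3.0)
        sk = skeletonize(m)
        a = extract_graph(sk, m, (1.0, 1.0, 1.0)).segments[0]
        b = extract_graph(sk, m, (2.0, 2.0, 2.0)).segments[0]
        assert b.length == pytest.approx(2 * a.length, rel=1e-6)


class TestBulgeSize:
    def test_formula_plugin(self):
        assert bulge_size(50.0, 10.0, 8.0) == pytest.approx(5.0)

    def test_clamped_at_zero_for_short_stubs(self):
        assert bulge_size(5.0, 10.0, 4.0) == 0.0

    def test_dimensionless_scale_invariance(self, rng):
        for _ in range(20):
            l, p, d = rng.uniform(1, 100, 3)
            k = rng.uniform(0.1, 50)
            assert bulge_size(k * l, k * p, k * d) == pytest.approx(bulge_size(l, p, d))

    def test_degenerate_diameter_rejected(self):
        with pytest.raises(ValueError):
            bulge_size(10.0, 1.0, 0.0)


class TestPruning:
    @pytest.fixture(scope="class")
    def stub_case(self):
        spec = PhantomSpec(
            rng_seed=3, dims=(160, 160, 160), n_bifurcations=3, radius_root=3.5,
            radius_decay=0.9, stub_count=3, stub_radius=2.0,
        )
        gt = generate_tree(spec)
        vg = extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing)
        return spec, gt, vg

    def test_threshold_zero_prunes_nothing(self, stub_case):
        spec, gt, vg0 = stub_case
        before = (vg0.n_nodes, vg0.n_segments)
        vg = extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing)
        prune_graph(vg, 0.0)
        assert (vg.n_nodes, vg.n_segments) == before

    def test_stubs_removed_true_branches_kept(self, stub_case):
        spec, gt, _ = stub_case
        vg = extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing)
        prune_graph(vg, 3.0)
        assert (vg.n_nodes, vg.n_segments) == (gt.n_nodes, gt.n_segments)
        assert branch_recall(gt, vg) == 1.0

    def test_monotone_in_threshold(self, stub_case):
        spec, gt, _ = stub_case
        counts = []
        for t in (0.5, 1.5, 3.0, 6.0):
            vg = extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing)
            prune_graph(vg, t)
            counts.append(vg.n_segments)
        assert counts == sorted(counts, reverse=True)

    def test_total_length_conserved_by_degree2_merge(self, stub_case):
        """Removing one stub merges its split-through parent; length of the
        surviving true tree is unchanged."""
        spec, gt, _ = stub_case
        vg = extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing)
        pre_lengths = sum(s.length for s in vg.segments)
        stub_lengths = 0.0
        prune_graph(vg, 3.0)
        assert vg.total_length() <= pre_lengths
        # all survivors are at/above threshold; no prunable leaf remains
        for s in vg.segments:
            da, db = vg.degree(s.node_a), vg.degree(s.node_b)
            if (da == 1) != (db == 1):
                parent = s.node_b if da == 1 else s.node_a
                d_bif = s.diameter_at_a if s.node_a == parent else s.diameter_at_b
                assert bulge_size(s.length, vg.node(parent).radius_at_node, d_bif) >= 3.0

    def test_isolated_segment_never_pruned(self):
        m = _tube_mask((40, 16, 16), (4, 8, 8), (36, 8, 8), 3.0)
        vg = extract_graph(skeletonize(m), m, (1.0, 1.0, 1.0))
        prune_graph(vg, 100.0)
        assert vg.n_segments == 1

    def test_scale_invariance_of_pruning_decisions(self):
        """The same tree rendered at doubled spacing and geometry prunes to
        the same topology."""
        a = PhantomSpec(rng_seed=5, dims=(160,) * 3, spacing=(1, 1, 1), n_bifurcations=3,
                        radius_root=3.5, radius_decay=0.9, stub_count=2, stub_radius=2.0)
        b = PhantomSpec(rng_seed=5, dims=(160,) * 3, spacing=(2, 2, 2), n_bifurcations=3,
                        radius_root=7.0, radius_decay=0.9, stub_count=2, stub_radius=4.0)
        ga, gb = generate_tree(a), generate_tree(b)
        va = prune_graph(extract_graph(skeletonize(ga.mask), ga.mask, a.spacing), 3.0)
        vb = prune_graph(extract_graph(skeletonize(gb.mask), gb.mask, b.spacing), 3.0)
        assert (va.n_nodes, va.n_segments) == (vb.n_nodes, vb.n_segments)


class TestGraphIO:
    def test_roundtrip_preserves_all_metrics(self, tmp_path):
        spec = PhantomSpec(rng_seed=1, dims=(128,) * 3, n_bifurcations=1,
                           radius_root=3.5, radius_decay=0.9)
        gt = generate_tree(spec)
        vg = prune_graph(extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing), 3.0)
        write_graph(vg, tmp_path)
        back = read_graph(tmp_path)
        assert back.n_nodes == vg.n_nodes and back.n_segments == vg.n_segments
        for s1, s2 in zip(vg.segments, back.segments):
            assert s1.length == pytest.approx(s2.length, abs=1e-4)
            assert s1.avg_diameter == pytest.approx(s2.avg_diameter, abs=1e-4)
            assert s1.straightness == pytest.approx(s2.straightness, abs=1e-6)
            assert s1.volume == pytest.approx(s2.volume, rel=1e-4)
        assert (tmp_path / "graph.graphml").exists()
        assert (tmp_path / "centerlines.vtk").read_text().startswith("# vtk")

    def test_empty_graph_writes_valid_files(self, tmp_path):
        from hiervess.graph import VesselGraph

        write_graph(VesselGraph(), tmp_path)
        back = read_graph(tmp_path)
        assert back.n_nodes == 0 and back.n_segments == 0

    def test_csv_segment_count_matches_graphml(self, tmp_path):
        import networkx as nx
        import pandas as pd

        spec = PhantomSpec(rng_seed=2, dims=(128,) * 3, n_bifurcations=1,
                           radius_root=3.5, radius_decay=0.9)
        gt = generate_tree(spec)
        vg = prune_graph(extract_graph(skeletonize(gt.mask), gt.mask, spec.spacing), 3.0)
        write_graph(vg, tmp_path)
        n_csv = len(pd.read_csv(tmp_path / "segments.csv"))
        n_gml = nx.read_graphml(tmp_path / "graph.graphml").number_of_edges()
        assert n_csv == n_gml == vg.n_segments
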