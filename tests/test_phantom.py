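import numpy as np
import pytest

from hiervess.phantom import (
    PhantomSpec,
    branch_recall,
    generate_tree,
    make_seeds,
    rasterize,
)


class TestGenerateTree:
    def test_no_bifurcations_gives_single_segment(self):
        spec = PhantomSpec(rng_seed=0, dims=(64,) * 3, n_bifurcations=0,
                           radius_root=5.0, segment_length=(30, 36))
        gt = generate_tree(spec)
        assert gt.n_segments == 1 and gt.n_nodes == 2

    def test_same_seed_reproduces_identical_ground_truth(self):
        spec = PhantomSpec(rng_seed=7, dims=(128,) * 3, n_bifurcations=2,
                           radius_root=3.5, radius_decay=0.9)
        a, b = generate_tree(spec), generate_tree(spec)
        assert len(a.segments) == len(b.segments)
        for s, t in zip(a.segments, b.segments):
            assert np.allclose(s.start, t.start) and np.allclose(s.end, t.end)
        assert np.array_equal(a.mask, b.mask)

    def test_each_bifurcation_adds_one_leaf(self):
        spec = PhantomSpec(rng_seed=2, dims=(192,) * 3, n_bifurcations=5,
                           radius_root=3.5, radius_decay=0.9)
        gt = generate_tree(spec)
        assert gt.n_segments == 2 * 5 + 1
        assert len(gt.leaf_segments()) == 5 + 1

    def test_child_radii_decay(self):
        spec = PhantomSpec(rng_seed=2, dims=(160,) * 3, n_bifurcations=3,
                           radius_root=4.0, radius_decay=0.8)
        gt = generate_tree(spec)
        by_id = {s.id: s for s in gt.segments}
        for s in gt.segments:
            if s.parent is not None:
                assert s.radius == pytest.approx(by_id[s.parent].radius * 0.8)

    def test_impossible_volume_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(PhantomSpec(rng_seed=0, dims=(16,) * 3, radius_root=20.0))


class TestRasterize:
    def test_solid_tube_voxel_count_near_analytic_volume(self):
        spec = PhantomSpec(rng_seed=0, dims=(64,) * 3, n_bifurcations=0,
                           radius_root=6.0, segment_length=(30, 36))
        gt = generate_tree(spec)
        grid = rasterize(gt)
        bright = (grid.intensities > 100).sum()
        s = gt.segments[0]
        # rendered tube is a capsule: cylinder plus spherical end caps
        analytic = (np.pi * s.radius**2 * s.length + 4 / 3 * np.pi * s.radius**3) / np.prod(
            spec.spacing
        )
        assert bright == pytest.approx(analytic, rel=0.10)

    def test_hollow_mode_shows_double_line_profile(self):
        spec = PhantomSpec(rng_seed=2, dims=(96,) * 3, n_bifurcations=0,
                           radius_root=6.0, segment_length=(28, 34),
                           wall_mode="hollow", wall_thickness=0.35)
        gt = generate_tree(spec)
        grid = rasterize(gt)
        s = gt.segments[0]
        mid = (s.start + s.end) / 2
        v = np.round(mid - 0.5).astype(int)
        # a profile crossing the tube center: wall / lumen / wall
        prof = grid.intensities[v[0] - 9 : v[0] + 10, v[1], v[2]]
        bright = prof > 100
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bright.view(np.int8), 0])))
        # bright / dark lumen / bright: at least two separate bright bands
        assert bright.any() and (len(runs) + 1) // 2 >= 2

    def test_noise_free_rendering_is_deterministic(self):
        spec = PhantomSpec(rng_seed=3, dims=(64,) * 3, n_bifurcations=0,
                           radius_root=5.0, segment_length=(24, 30), noise_sigma=7.0)
        gt = generate_tree(spec)
        assert np.array_equal(rasterize(gt).intensities, rasterize(gt).intensities)

    def test_noise_respects_dtype_clipping(self):
        spec = PhantomSpec(rng_seed=3, dims=(48,) * 3, n_bifurcations=0,
                           radius_root=5.0, segment_length=(20, 26),
                           noise_sigma=120.0, dtype="uint8")
        gt = generate_tree(spec)
        grid = rasterize(gt)
        assert grid.intensities.dtype == np.uint8


class TestMakeSeeds:
    @pytest.fixture(scope="class")
    def case(self):
        spec = PhantomSpec(rng_seed=4, dims=(96,) * 3, n_bifurcations=2,
                           radius_root=5.0, segment_length=(22, 30))
        gt = generate_tree(spec)
        return spec, gt, make_seeds(gt)

    def test_fg_seeds_inside_true_mask(self, case):
        spec, gt, seeds = case
        assert seeds.foreground
        assert all(gt.mask[p] for p in seeds.foreground)

    def test_bg_seeds_outside_dilated_mask(self, case):
        from scipy import ndimage as ndi

        spec, gt, seeds = case
        dil = ndi.binary_dilation(gt.mask, iterations=2)
        assert seeds.background
        assert not any(dil[p] for p in seeds.background)

    def test_deterministic(self, case):
        spec, gt, seeds = case
        again = make_seeds(gt)
        assert again.foreground == seeds.foreground
        assert again.background == seeds.background

    def test_zero_strokes_gives_empty_foreground(self, case):
        spec, gt, _ = case
        s = make_seeds(gt, n_fg_strokes=0, n_bg_points=0, bg_grid=None)
        assert len(s.foreground) == 0 and len(s.background) == 0


class TestGroundTruthGraph:
    def test_vessel_graph_matches_analytic_totals(self):
        spec = PhantomSpec(rng_seed=1, dims=(128,) * 3, n_bifurcations=2,
                           radius_root=3.5, radius_decay=0.9)
        gt = generate_tree(spec)
        vg = gt.to_vessel_graph()
        assert vg.n_segments == gt.n_segments
        assert vg.total_length() == pytest.approx(gt.total_length, rel=1e-9)
        assert vg.total_volume() == pytest.approx(gt.total_volume, rel=1e-6)

    def test_branch_recall_is_one_against_own_graph(self):
        spec = PhantomSpec(rng_seed=1, dims=(128,) * 3, n_bifurcations=2,
                           radius_root=3.5, radius_decay=0.9)
        gt = generate_tree(spec)
        assert branch_recall(gt, gt.to_vessel_graph()) == 1.0
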