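import numpy as np
import pytest

from hiervess import build_octree
from hiervess.hierarchy import (
    DET_BG,
    ProbabilityVolume,
    DET_FG,
    HierarchyConfig,
    boundary_from_coarse,
    classify_homogeneous,
    incremental_update,
    run_hierarchical_rw,
    threshold_segmentation,
)
from hiervess.octree import BrickIndex
from hiervess.random_walker import RWConfig, flat_rw_oracle
from hiervess.phantom import PhantomSpec, generate_tree, make_seeds, rasterize
from hiervess.seeds import SeedSet
from hiervess.volume import VoxelGrid


class TestClassification:
    cfg = HierarchyConfig()

    def test_all_one_without_seeds_is_foreground(self):
        assert classify_homogeneous(np.ones(8), False, False, self.cfg) == "foreground"

    def test_opposite_seed_overrides_homogeneity(self):
        vals = np.full(8, 0.999)
        assert classify_homogeneous(vals, False, True, self.cfg) == "mixed"

    def test_mixture_is_mixed(self):
        assert classify_homogeneous(np.array([0.0, 1.0]), False, False, self.cfg) == "mixed"

    def test_all_zero_is_background(self):
        assert classify_homogeneous(np.zeros(8), False, False, self.cfg) == "background"


class TestBoundaryFromCoarse:
    def _prob_with_root(self, pyr, root_values):
        prob = ProbabilityVolume(pyr)
        b = pyr.brick_size
        padded = np.zeros((b, b, b))
        d = pyr.level_dims(pyr.n_levels - 1)
        padded[: d[0], : d[1], : d[2]] = root_values
        prob.store.put(BrickIndex(pyr.n_levels - 1, 0, 0, 0), padded)
        prob.status[pyr.n_levels - 1][0, 0, 0] = 1
        return prob

    @pytest.fixture()
    def two_level_pyr(self, rng):
        g = VoxelGrid(rng.integers(0, 255, (16, 16, 16)).astype(np.uint8))
        return build_octree(g, brick_size=8)

    def test_constant_parent_gives_constant_shell(self, two_level_pyr):
        pyr = two_level_pyr
        prob = self._prob_with_root(pyr, np.ones(pyr.level_dims(1)))
        shell = boundary_from_coarse(prob, pyr, BrickIndex(0, 0, 0, 0))
        assert shell and all(v == 1.0 for v in shell.values())

    def test_nearest_mode_respects_halfspace_split(self, two_level_pyr):
        pyr = two_level_pyr
        root = np.zeros(pyr.level_dims(1))
        root[4:, :, :] = 1.0  # right half foreground at coarse level
        prob = self._prob_with_root(pyr, root)
        shell = boundary_from_coarse(prob, pyr, BrickIndex(0, 0, 0, 0), mode="nearest")
        for (x, y, z), v in shell.items():
            assert v == (1.0 if (x + 0.5) / 2 - 0.5 > 3.5 else 0.0)

    def test_trilinear_is_monotone_across_interface(self, two_level_pyr):
        pyr = two_level_pyr
        root = np.zeros(pyr.level_dims(1))
        root[4:, :, :] = 1.0
        prob = self._prob_with_root(pyr, root)
        shell = boundary_from_coarse(prob, pyr, BrickIndex(0, 0, 0, 0), mode="trilinear")
        ys = sorted({(x, v) for (x, y, z), v in shell.items() if y == 4 and z == 0})
        vals = [v for _, v in ys]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert any(0.0 < v < 1.0 for v in vals)

    def test_unsolved_parent_is_sequencing_error(self, two_level_pyr):
        pyr = two_level_pyr
        prob = ProbabilityVolume(pyr)
        with pytest.raises(RuntimeError, match="not yet solved"):
            boundary_from_coarse(prob, pyr, BrickIndex(0, 0, 0, 0))


def _tube_case(seed, dims=(64, 64, 64), **kw):
    spec = PhantomSpec(
        rng_seed=seed, dims=dims, n_bifurcations=0, radius_root=10.0,
        segment_length=(26, 36), **kw,
    )
    gt = generate_tree(spec)
    grid = rasterize(gt)
    seeds = make_seeds(gt)
    return spec, gt, grid, seeds


class TestHierarchicalSolver:
    def test_single_brick_volume_reproduces_flat_solver_bitwise(self):
        spec = PhantomSpec(
            rng_seed=0, dims=(24, 24, 24), n_bifurcations=0, radius_root=4.0,
            segment_length=(8, 12),
        )
        gt = generate_tree(spec)
        grid = rasterize(gt)
        seeds = make_seeds(gt, n_bg_points=10)
        pyr = build_octree(grid, brick_size=32)
        assert pyr.n_levels == 1
        prob = run_hierarchical_rw(pyr, seeds)
        flat = flat_rw_oracle(grid.intensities.astype(float), seeds, RWConfig())
        assert np.array_equal(prob.level_array(0), flat)

    def test_oracle_closeness_on_multibrick_phantom(self):
        spec, gt, grid, seeds = _tube_case(1)
        pyr = build_octree(grid, brick_size=32)
        prob = run_hierarchical_rw(pyr, seeds, cache_budget=16)
        flat = flat_rw_oracle(grid.intensities.astype(float), seeds, RWConfig())
        p0 = prob.level_array(0)
        assert np.abs(p0 - flat).max() <= 0.05
        assert ((p0 >= 0.5) != (flat >= 0.5)).mean() <= 0.01

    def test_background_octants_pruned_at_coarse_level(self, small_tree, small_tree_pyramid):
        """Bricks far from the tree are classified without solving."""
        spec, gt, grid, seeds = small_tree
        prob = run_hierarchical_rw(small_tree_pyramid, seeds, cache_budget=32)
        st = prob.stats[0]
        total = st["solved"] + st["determined"]
        assert st["determined"] > 0
        assert st["solved"] < 0.4 * total
        # determined bricks agree with the flat oracle almost everywhere
        flat_mask = (
            flat_rw_oracle(grid.intensities.astype(float), seeds, RWConfig()) >= 0.5
        )
        hier_mask = threshold_segmentation(prob)
        det = np.zeros(spec.dims, bool)
        b = small_tree_pyramid.brick_size
        for (bx, by, bz), s in np.ndenumerate(prob.status[0]):
            if s in (DET_FG, DET_BG):
                det[bx * b:(bx + 1) * b, by * b:(by + 1) * b, bz * b:(bz + 1) * b] = True
        agree = (hier_mask == flat_mask)[det].mean()
        assert agree >= 0.999

    def test_deterministic_across_runs(self, small_tree, small_tree_pyramid):
        spec, gt, grid, seeds = small_tree
        a = run_hierarchical_rw(small_tree_pyramid, seeds).level_array(0)
        b = run_hierarchical_rw(small_tree_pyramid, seeds).level_array(0)
        assert np.array_equal(a, b)

    def test_missing_seed_class_rejected(self, small_tree_pyramid):
        with pytest.raises(ValueError):
            run_hierarchical_rw(small_tree_pyramid, SeedSet({(1, 1, 1)}, set()))


class TestThreshold:
    def test_tie_value_is_foreground(self, small_tree, small_tree_pyramid):
        spec, gt, grid, seeds = small_tree
        prob = run_hierarchical_rw(small_tree_pyramid, seeds)
        p0 = prob.level_array(0)
        mask = threshold_segmentation(prob)
        assert np.array_equal(mask, p0 >= 0.5)

    def test_complement_masks_partition_volume(self, small_tree, small_tree_pyramid):
        spec, gt, grid, seeds = small_tree
        prob = run_hierarchical_rw(small_tree_pyramid, seeds)
        p0 = prob.level_array(0)
        mask = threshold_segmentation(prob)
        comp = (1.0 - p0) >= 0.5
        ties = p0 == 0.5
        assert np.array_equal(mask | comp | ties, np.ones_like(mask))


class TestIncrementalUpdate:
    def test_unchanged_seeds_reuse_everything_bit_identically(
        self, small_tree, small_tree_pyramid
    ):
        spec, gt, grid, seeds = small_tree
        prob = run_hierarchical_rw(small_tree_pyramid, seeds, cache_budget=32)
        inc = incremental_update(prob, small_tree_pyramid, seeds, seeds, cache_budget=32)
        assert sum(s["solved"] for s in inc.stats.values()) == 0
        assert np.array_equal(prob.level_array(0), inc.level_array(0))

    def test_local_edit_resolves_few_bricks_and_matches_scratch(
        self, small_tree, small_tree_pyramid
    ):
        spec, gt, grid, seeds = small_tree
        pyr = small_tree_pyramid
        prob = run_hierarchical_rw(pyr, seeds, cache_budget=32)
        tip = gt.segments[-1]
        p = tip.start + 0.9 * (tip.end - tip.start)
        v = tuple(np.clip((p - 0.5).round().astype(int), 0, np.array(spec.dims) - 1))
        new_seeds = SeedSet(set(seeds.foreground) | {v}, set(seeds.background))
        inc = incremental_update(prob, pyr, seeds, new_seeds, cache_budget=32)
        scratch = run_hierarchical_rw(pyr, new_seeds, cache_budget=32)
        resolved = sum(s["solved"] for s in inc.stats.values())
        total = sum(s["solved"] for s in scratch.stats.values())
        assert 0 < resolved < total
        assert np.abs(inc.level_array(0) - scratch.level_array(0)).max() <= 0.05

    def test_mismatched_pyramid_rejected(self, small_tree, small_tree_pyramid, rng):
        spec, gt, grid, seeds = small_tree
        prob = run_hierarchical_rw(small_tree_pyramid, seeds)
        other = build_octree(
            VoxelGrid(rng.integers(0, 255, (48, 48, 48)).astype(np.uint8)), 32
        )
        with pytest.raises(ValueError):
            incremental_update(prob, other, seeds, seeds)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"binary_threshold": 0.0},
            {"homogeneity_eps": 0.7},
            {"upsample_mode": "cubic"},
        ],
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            HierarchyConfig(**kw)
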