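import numpy as np
import pytest

from hiervess import build_octree
from hiervess.phantom import PhantomSpec, generate_tree, make_seeds, rasterize


@pytest.fixture(scope="session")
def small_tree():
    """A 96³ two-bifurcation solid phantom with rendered volume and seeds."""
    spec = PhantomSpec(
        rng_seed=4, dims=(96, 96, 96), n_bifurcations=2, radius_root=5.0,
        segment_length=(22, 30),
    )
    gt = generate_tree(spec)
    grid = rasterize(gt)
    seeds = make_seeds(gt)
    return spec, gt, grid, seeds


@pytest.fixture(scope="session")
def small_tree_pyramid(small_tree):
    spec, gt, grid, seeds = small_tree
    return build_octree(grid, brick_size=32, cache_budget=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
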