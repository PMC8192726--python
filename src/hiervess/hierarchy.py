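"""Coarse-to-fine hierarchical random-walker segmentation over the octree.

The probability map is first solved on the single coarse root brick using
the user seeds scaled down to that level.  It is then refined top-down,
level by level, brick after brick: each finer brick is solved with the hard
seeds that fall inside it plus soft Dirichlet values on its face shell,
sampled (nearest or trilinear) from the already-solved coarser level — the
coarse probabilities act as non-binary seeds at the brick border, so the
general shape of structures propagates down while fine levels refine object
borders.

Two prunings keep the work far below "solve every brick":

* homogeneous-branch pruning — a brick whose coarse footprint is entirely
  foreground (or background) within ``homogeneity_eps``, and which contains
  no seed of the opposite class, is filled with a constant and its whole
  subtree of finer bricks is skipped;
* incremental reuse — on a re-run with edited seeds, a brick is re-solved
  only if its seed content changed or its coarse-supplied boundary values
  moved by more than ``reuse_eps`` (L-infinity); otherwise the previous
  result is reused verbatim.

Cross-brick coupling flows exclusively through the coarser level, so bricks
within one level are independent and the result does not depend on the
order in which they are processed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .octree import BrickIndex, BrickStore, OctreePyramid
from .random_walker import RWConfig, solve_random_walker
from .seeds import SeedSet, scale_seeds_to_level

# brick status codes
UNSOLVED, SOLVED, DET_FG, DET_BG = 0, 1, 2, 3


@dataclass
class HierarchyConfig:
    binary_threshold: float = 0.5
    homogeneity_eps: float = 0.01
    reuse_eps: float = 0.01
    upsample_mode: str = "trilinear"  # or "nearest"
    # Border values are imposed only where the coarse level is decided
    # (within shell_confidence_eps of 0 or 1) and not directly adjacent to
    # the coarse transition zone (one erosion step along the shell).  Shell
    # voxels in or next to the transition zone are left free, so the fine
    # solve positions the object boundary from local contrast instead of
    # inheriting the coarse interpolation ramp, which can misplace it by a
    # fine voxel.  0.5 disables the filter (clamp everything).
    shell_confidence_eps: float = 0.02
    # Each brick is solved on a domain extended by this many voxels so that
    # structures clipped off at a brick face or corner stay connected to
    # their context (and to any nearby seeds); only the brick's own voxels
    # are written back.  The Dirichlet shell sits on the extended domain.
    halo: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.binary_threshold < 1.0:
            raise ValueError("binary_threshold must be in (0, 1)")
        if not 0.0 < self.homogeneity_eps < 0.5:
            raise ValueError("homogeneity_eps must be in (0, 0.5)")
        if not 0.0 <= self.reuse_eps < 0.5:
            raise ValueError("reuse_eps must be in [0, 0.5)")
        if self.upsample_mode not in ("nearest", "trilinear"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")


class ProbabilityVolume:
    """Per-level, per-brick foreground probability map with completeness flags.

    A brick is either solved (stores the harmonic solution), or determined
    (stores a constant 0 or 1 from homogeneous-branch pruning), or not yet
    touched.  Per-brick provenance records (seed content and the boundary
    values actually imposed) support the incremental-reuse rule.
    """

    def __init__(self, pyr: OctreePyramid, cache_budget: int = 64, path: str | None = None):
        self.store = BrickStore(
            path, pyr.dims, pyr.brick_size, pyr.n_levels,
            cache_budget=cache_budget, dtype=np.float64,
        )
        self.status = {
            lv: np.zeros(pyr.brick_counts(lv), dtype=np.int8)
            for lv in range(pyr.n_levels)
        }
        self.records: dict[tuple, dict] = {}
        self.stats: dict = {}

    def level_array(self, level: int = 0) -> np.ndarray:
        if not (self.status[level] != UNSOLVED).all():
            raise RuntimeError(f"level {level} probability map incomplete")
        return self.store.read_region(level, (0, 0, 0), self.store.dims(level))

    def close(self) -> None:
        self.store.close()


def _brick_box(store: BrickStore, idx: BrickIndex):
    """Global [lo, hi) voxel box of the valid (non-padding) brick extent."""
    b = store.brick_size
    lo = tuple(c * b for c in idx.coords)
    ve = store.valid_extent(idx)
    hi = tuple(l + e for l, e in zip(lo, ve))
    return lo, hi


def classify_homogeneous(
    coarse_vals: np.ndarray,
    has_fg_seed: bool,
    has_bg_seed: bool,
    cfg: HierarchyConfig,
) -> str:
    """Classify a brick footprint as foreground / background / mixed.

    Foreground iff every coarse probability is >= 1 - homogeneity_eps and no
    background seed lies inside the brick (a seed always overrides the
    coarse consensus); symmetrically for background.
    """
    eps = cfg.homogeneity_eps
    if coarse_vals.size and coarse_vals.min() >= 1.0 - eps and not has_bg_seed:
        return "foreground"
    if coarse_vals.size and coarse_vals.max() <= eps and not has_fg_seed:
        return "background"
    return "mixed"


def _shell_coords(lo, hi, dims) -> np.ndarray:
    """Global coordinates of the brick's one-voxel face shell, restricted to
    faces that adjoin another brick (volume-hull faces stay unconstrained,
    matching the flat solver's natural boundary)."""
    shape = tuple(h - l for l, h in zip(lo, hi))
    m = np.zeros(shape, dtype=bool)
    for ax in range(3):
        if lo[ax] > 0:
            sl = [slice(None)] * 3
            sl[ax] = slice(0, 1)
            m[tuple(sl)] = True
        if hi[ax] < dims[ax]:
            sl = [slice(None)] * 3
            sl[ax] = slice(shape[ax] - 1, shape[ax])
            m[tuple(sl)] = True
    return np.argwhere(m) + np.asarray(lo)


def boundary_from_coarse(
    prob: ProbabilityVolume,
    pyr: OctreePyramid,
    idx: BrickIndex,
    mode: str = "trilinear",
) -> dict:
    """Sample coarse-level probabilities onto the face shell of a finer brick.

    Fine voxel centers map to parent-level index space via
    ``(i + 0.5)/2 - 0.5``; the parent map is interpolated there (order 0 for
    nearest, order 1 for trilinear).  Raises if the parent footprint has not
    been solved or determined yet.
    """
    lo, hi = _brick_box(prob.store, idx)
    return _coarse_shell_values(prob, pyr, idx.level, lo, hi, mode)


def _coarse_shell_values(
    prob: ProbabilityVolume,
    pyr: OctreePyramid,
    level: int,
    lo,
    hi,
    mode: str,
) -> dict:
    """Coarse-map values for the seam shell of an arbitrary box at a level."""
    parent_level = level + 1
    if parent_level >= pyr.n_levels:
        raise ValueError("root brick has no coarser level")
    pdims = prob.store.dims(parent_level)
    plo = tuple(max(l // 2 - 1, 0) for l in lo)
    phi = tuple(min((h - 1) // 2 + 2, d) for h, d in zip(hi, pdims))
    pstat = prob.status[parent_level]
    for cx in range(plo[0] // prob.store.brick_size, (phi[0] - 1) // prob.store.brick_size + 1):
        for cy in range(plo[1] // prob.store.brick_size, (phi[1] - 1) // prob.store.brick_size + 1):
            for cz in range(plo[2] // prob.store.brick_size, (phi[2] - 1) // prob.store.brick_size + 1):
                if pstat[cx, cy, cz] == UNSOLVED:
                    raise RuntimeError(
                        f"parent brick ({cx},{cy},{cz}) of a level-{level} box "
                        f"at {lo} not yet solved"
                    )
    region = prob.store.read_region(parent_level, plo, phi)
    coords = _shell_coords(lo, hi, prob.store.dims(level))
    if coords.size == 0:
        return {}
    pc = (coords + 0.5) / 2.0 - 0.5 - np.asarray(plo)
    order = 1 if mode == "trilinear" else 0
    vals = map_coordinates(region, pc.T, order=order, mode="nearest")
    vals = np.clip(vals, 0.0, 1.0)
    local = coords - np.asarray(lo)
    return {tuple(p): float(v) for p, v in zip(local, vals)}


def _confident_shell(bvals: dict, eps: float) -> dict:
    """Filter shell values to the eroded confident set.

    Keeps values within ``eps`` of 0 or 1 whose 26-neighborhood on the
    shell contains no transition-zone value; clamps are thereby placed
    strictly inside regions the coarse level decided.
    """
    if eps >= 0.5:
        return dict(bvals)
    conf = {p for p, v in bvals.items() if v <= eps or v >= 1.0 - eps}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    out = {}
    for p in conf:
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if q in bvals and q not in conf:
                break
        else:
            out[p] = bvals[p]
    return out


def _seeds_in_box(seeds: SeedSet, lo, hi):
    inside = lambda p: all(l <= c < h for c, l, h in zip(p, lo, hi))
    fg = any(inside(p) for p in seeds.foreground)
    bg = any(inside(p) for p in seeds.background)
    return fg, bg


def _solve_box(
    pyr: OctreePyramid,
    level: int,
    lo,
    hi,
    level_seeds: SeedSet,
    boundary: dict,
    rw_cfg: RWConfig,
) -> np.ndarray:
    vol = pyr.store.read_region(level, lo, hi).astype(np.float64)
    cfg = RWConfig(
        beta=rw_cfg.beta,
        solver_tol=rw_cfg.solver_tol,
        max_iter=rw_cfg.max_iter,
        intensity_scale=rw_cfg.intensity_scale or pyr.intensity_scale,
    )
    return solve_random_walker(
        vol,
        seeds=level_seeds,
        boundary=boundary,
        cfg=cfg,
        spacing=pyr.level_spacing(level),
        offset=lo,
    )


def _write_brick_values(prob: ProbabilityVolume, idx: BrickIndex, values: np.ndarray):
    b = prob.store.brick_size
    padded = np.zeros((b, b, b), dtype=np.float64)
    padded[: values.shape[0], : values.shape[1], : values.shape[2]] = values
    prob.store.put(idx, padded)


def run_hierarchical_rw(
    pyr: OctreePyramid,
    seeds: SeedSet,
    cfg: HierarchyConfig | None = None,
    rw_cfg: RWConfig | None = None,
    cache_budget: int = 64,
    _prev: Optional[ProbabilityVolume] = None,
    _old_seeds: Optional[SeedSet] = None,
) -> ProbabilityVolume:
    """Top-down hierarchical random-walker refinement.

    Requires at least one foreground and one background seed (level-0
    coordinates).  Returns the multi-level :class:`ProbabilityVolume`;
    ``.stats`` records per-level solved / determined / reused brick counts.
    """
    cfg = cfg or HierarchyConfig()
    rw_cfg = rw_cfg or RWConfig()
    if not seeds.foreground or not seeds.background:
        raise ValueError("need at least one foreground and one background seed")
    seeds.validate_inside(pyr.dims)

    prob = ProbabilityVolume(pyr, cache_budget=cache_budget)
    top = pyr.n_levels - 1
    scaled = {lv: scale_seeds_to_level(seeds, lv) for lv in range(pyr.n_levels)}
    old_scaled = (
        {lv: scale_seeds_to_level(_old_seeds, lv) for lv in range(pyr.n_levels)}
        if _old_seeds is not None
        else None
    )

    for level in range(top, -1, -1):
        lv_seeds = scaled[level]
        nsolved = ndet = nreused = 0
        nb = pyr.brick_counts(level)
        for bx in range(nb[0]):
            for by in range(nb[1]):
                for bz in range(nb[2]):
                    idx = BrickIndex(level, bx, by, bz)
                    lo, hi = _brick_box(pyr.store, idx)
                    key = (level, bx, by, bz)
                    if level == top:
                        rec = {"kind": "root", "seed_sig": lv_seeds.signature_in_box(lo, hi)}
                        if _prev is not None and _reusable_root(
                            _prev, old_scaled[level] if old_scaled else None, key, lo, hi, rec
                        ):
                            _copy_brick(_prev, prob, idx, rec)
                            nreused += 1
                        else:
                            vals = _solve_box(pyr, level, lo, hi, lv_seeds, {}, rw_cfg)
                            _write_brick_values(prob, idx, vals)
                            nsolved += 1
                        prob.status[level][bx, by, bz] = SOLVED
                        prob.records[key] = rec
                        continue

                    # classify against the coarse footprint, padded by one
                    # coarse voxel: structures thinner than a coarse voxel
                    # that poke across a brick face are invisible in the
                    # unpadded footprint but show in the neighboring cell
                    pdims = prob.store.dims(level + 1)
                    plo = tuple(max(l // 2 - 1, 0) for l in lo)
                    phi = tuple(
                        min((h - 1) // 2 + 2, d) for h, d in zip(hi, pdims)
                    )
                    coarse = prob.store.read_region(level + 1, plo, phi)
                    has_fg, has_bg = _seeds_in_box(lv_seeds, lo, hi)
                    cls = classify_homogeneous(coarse, has_fg, has_bg, cfg)
                    if cls != "mixed":
                        const = 1.0 if cls == "foreground" else 0.0
                        ve = tuple(h - l for l, h in zip(lo, hi))
                        _write_brick_values(prob, idx, np.full(ve, const))
                        prob.status[level][bx, by, bz] = (
                            DET_FG if cls == "foreground" else DET_BG
                        )
                        prob.records[key] = {"kind": "det", "const": const}
                        ndet += 1
                        continue

                    # halo-extended solve domain: clipped structures keep
                    # their context; Dirichlet shell sits on the domain
                    h = cfg.halo
                    dims_l = pyr.level_dims(level)
                    dlo = tuple(max(l - h, 0) for l in lo)
                    dhi = tuple(min(x + h, d) for x, d in zip(hi, dims_l))
                    all_bvals = _coarse_shell_values(
                        prob, pyr, level, dlo, dhi, cfg.upsample_mode
                    )
                    confident = _confident_shell(all_bvals, cfg.shell_confidence_eps)
                    if not confident:
                        # no decided coarse values anywhere on this shell
                        # (e.g. noisy two-level pyramids): solve with a full
                        # brick of extra context instead
                        h = pyr.brick_size
                        dlo = tuple(max(l - h, 0) for l in lo)
                        dhi = tuple(min(x + h, d) for x, d in zip(hi, dims_l))
                        all_bvals = _coarse_shell_values(
                            prob, pyr, level, dlo, dhi, cfg.upsample_mode
                        )
                        confident = _confident_shell(all_bvals, cfg.shell_confidence_eps)
                    dfg, dbg = _seeds_in_box(lv_seeds, dlo, dhi)
                    # keep at least one constraint so the solve is determined
                    bvals = confident if (confident or dfg or dbg) else all_bvals
                    rec = {
                        "kind": "mixed",
                        "seed_sig": lv_seeds.signature_in_box(dlo, dhi),
                        "boundary": bvals,
                    }
                    if _prev is not None and _reusable_mixed(
                        _prev, old_scaled[level] if old_scaled else None,
                        key, lo, hi, rec, cfg.reuse_eps,
                    ):
                        _copy_brick(_prev, prob, idx, rec)
                        nreused += 1
                    else:
                        vals = _solve_box(pyr, level, dlo, dhi, lv_seeds, bvals, rw_cfg)
                        crop = tuple(
                            slice(l - dl, h_ - dl) for l, h_, dl in zip(lo, hi, dlo)
                        )
                        _write_brick_values(prob, idx, vals[crop])
                        nsolved += 1
                    prob.status[level][bx, by, bz] = SOLVED
                    prob.records[key] = rec
        prob.stats[level] = {"solved": nsolved, "determined": ndet, "reused": nreused}
    return prob


def _reusable_root(prev, old_lv_seeds, key, lo, hi, rec) -> bool:
    old = prev.records.get(key)
    return (
        old is not None
        and old.get("kind") == "root"
        and old.get("seed_sig") == rec["seed_sig"]
    )


def _reusable_mixed(prev, old_lv_seeds, key, lo, hi, rec, reuse_eps) -> bool:
    old = prev.records.get(key)
    if old is None or old.get("kind") != "mixed":
        return False
    if old.get("seed_sig") != rec["seed_sig"]:
        return False
    ob, nb_ = old["boundary"], rec["boundary"]
    if ob.keys() != nb_.keys():
        return False
    if ob:
        diff = max(abs(ob[k] - nb_[k]) for k in ob)
        if diff > reuse_eps:
            return False
    return True


def _copy_brick(prev: ProbabilityVolume, prob: ProbabilityVolume, idx: BrickIndex, rec: dict):
    data = prev.store.get(idx)
    prob.store.put(idx, np.array(data))
    # reuse is verbatim: keep the boundary actually imposed on the old solve
    old = prev.records[(idx.level, *idx.coords)]
    if "boundary" in old:
        rec["boundary"] = old["boundary"]


def incremental_update(
    prev: ProbabilityVolume,
    pyr: OctreePyramid,
    old_seeds: SeedSet,
    new_seeds: SeedSet,
    cfg: HierarchyConfig | None = None,
    rw_cfg: RWConfig | None = None,
    cache_budget: int = 64,
) -> ProbabilityVolume:
    """Re-run segmentation after a seed edit, reusing unchanged bricks.

    A brick is re-solved only if its seed content changed or the boundary
    values supplied by its (possibly updated) parent level moved by more
    than ``reuse_eps`` in L-infinity; all other bricks are copied verbatim
    from the previous result.
    """
    if prev.store.dims0 != pyr.dims or prev.store.brick_size != pyr.brick_size:
        raise ValueError("previous probability volume does not match this pyramid")
    return run_hierarchical_rw(
        pyr, new_seeds, cfg, rw_cfg, cache_budget=cache_budget,
        _prev=prev, _old_seeds=old_seeds,
    )


def threshold_segmentation(prob: ProbabilityVolume, cfg: HierarchyConfig | None = None) -> np.ndarray:
    """Binary segmentation: foreground iff p >= binary_threshold (tie -> fg)."""
    cfg = cfg or HierarchyConfig()
    return prob.level_array(0) >= cfg.binary_threshold
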