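"""Synthetic branching-vessel phantoms with exact ground truth.

Stands in for cleared-organ light-sheet acquisitions of stained
vasculature: a seeded recursive binary tree of straight tubular segments is
rendered into an intensity volume either solid or hollow — hollow mode
brightens only a wall shell so tube cross-sections show the "double line"
appearance of lumen-bearing vessels — with additive Gaussian noise.  The
generator returns the exact centerline graph, radii, binary mask and
totals, so every downstream stage (segmentation, graph extraction, pruning,
morphometrics) can be validated against construction.

Short stub branches (length below the pruning threshold times their
diameter) can be injected at bifurcations to exercise bulge-size pruning:
stubs are rendered into the volume and mask but excluded from the
ground-truth topology.

Simplifications relative to real LSFM data (see docs/methods.md): additive
Gaussian noise only (no PSF blur, shot noise or stripe artifacts), straight
segments, constant radius per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .seeds import SeedSet
from .volume import VoxelGrid


@dataclass
class PhantomSpec:
    """Parameters of one synthetic vessel tree.

    Lengths and radii are micrometers.  Defaults give a small, clearly
    resolved tree: tube radii of several voxels at unit spacing, strong
    foreground/background contrast, and noise off.
    """

    rng_seed: int = 0
    dims: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    n_bifurcations: int = 2
    radius_root: float = 5.0
    radius_decay: float = 0.85  # child radius = parent radius x decay
    # segment length drawn as factor x segment diameter, so every true
    # branch reaches well beyond the bulge-size pruning threshold of 3
    segment_length_factor: tuple = (5.5, 7.5)
    segment_length: tuple | None = None  # absolute µm range override
    wall_mode: str = "solid"  # or "hollow"
    wall_thickness: float = 0.4  # fraction of the radius, hollow mode
    fg_intensity: float = 200.0
    bg_intensity: float = 20.0
    noise_sigma: float = 0.0
    dtype: str = "uint8"
    # stub injection for pruning tests: n stubs of length factor x diameter
    stub_count: int = 0
    stub_length_factor: float = 1.5
    stub_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius_root <= 0 or not 0 < self.radius_decay <= 1:
            raise ValueError("radii must be positive, decay in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.wall_mode not in ("solid", "hollow"):
            raise ValueError(f"unknown wall_mode {self.wall_mode!r}")


@dataclass
class TreeSegment:
    id: int
    start: np.ndarray  # physical µm
    end: np.ndarray
    radius: float
    parent: int | None  # parent segment id
    is_stub: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / max(self.length, 1e-12)


@dataclass
class GroundTruth:
    spec: PhantomSpec
    segments: list = field(default_factory=list)  # true tree (no stubs)
    stubs: list = field(default_factory=list)
    mask: np.ndarray | None = None  # filled (solid) true mask

    # -- exact topology of the true tree (each bifurcation adds 2 segments,
    # 1 branch node and net 1 leaf) ------------------------------------------
    @property
    def n_bifurcations(self) -> int:
        return (len(self.segments) - 1) // 2

    @property
    def n_branch_nodes(self) -> int:
        return self.n_bifurcations

    @property
    def n_endpoint_nodes(self) -> int:
        return self.n_bifurcations + 2  # root start + leaves

    @property
    def n_nodes(self) -> int:
        return self.n_branch_nodes + self.n_endpoint_nodes

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def total_volume(self) -> float:
        return sum(np.pi * s.radius**2 * s.length for s in self.segments)

    def leaf_segments(self) -> list:
        parents = {s.parent for s in self.segments if s.parent is not None}
        return [s for s in self.segments if s.id not in parents]

    def to_vessel_graph(self, points_per_segment: int = 50):
        """Exact ground-truth graph as a VesselGraph (analytic centerlines).

        Centerlines are straight polylines with constant radius, so derived
        metrics (length, straightness, cone-quadrature volume) can be
        checked against closed forms.
        """
        from .graph import VesselGraph

        vg = VesselGraph()
        node_at: dict[tuple, int] = {}

        def node_for(point: np.ndarray, radius: float) -> int:
            key = tuple(np.round(point, 9))
            if key not in node_at:
                node_at[key] = vg.add_node(point, "endpoint", radius)
            return node_at[key]

        for s in self.segments:
            a = node_for(s.start, s.radius)
            b = node_for(s.end, s.radius)
            t = np.linspace(0.0, 1.0, max(points_per_segment, 2))
            line = s.start + t[:, None] * (s.end - s.start)
            radii = np.full(len(t), s.radius)
            vg.add_segment(a, b, line, radii, 2 * s.radius, 2 * s.radius)
        vg.refresh_kinds()
        return vg


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _perp_basis(d: np.ndarray):
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, a))
    return u, np.cross(d, u)


def _rotate_from(d: np.ndarray, polar: float, azimuth: float) -> np.ndarray:
    u, v = _perp_basis(d)
    return _unit(
        np.cos(polar) * d + np.sin(polar) * (np.cos(azimuth) * u + np.sin(azimuth) * v)
    )


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def generate_tree(spec: PhantomSpec) -> GroundTruth:
    """Grow a seeded binary branching tree of straight tube segments.

    Bifurcations are inserted sequentially at random leaf tips; each insert
    converts a leaf into a degree-3 branch node and adds two children with
    radius = parent radius x decay and branch angles of 20-60 degrees from
    the parent axis (azimuths roughly opposed so siblings separate cleanly).
    Candidate segments that leave the volume or pass too close to an
    existing non-adjacent segment are re-sampled up to a retry cap.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ext = np.asarray(spec.dims) * np.asarray(spec.spacing)
    margin0 = spec.radius_root + 2 * max(spec.spacing)

    def margin_for(r):
        return r + 2 * max(spec.spacing)

    def inside(p, r):
        m = margin_for(r)
        return bool(np.all(p >= m) and np.all(p <= ext - m))

    def clear_of_others(a, b, r, exclude_ids, pad=None):
        # > 1 voxel so separately generated tubes cannot fuse when rasterized
        pad = 2.0 * max(spec.spacing) if pad is None else pad
        for s in segs:
            if s.id in exclude_ids:
                continue
            for t in np.linspace(0.0, 1.0, 12):
                p = a + t * (b - a)
                if _point_segment_dist(p, s.start, s.end) < r + s.radius + pad:
                    return False
        return True

    def draw_length(radius: float) -> float:
        if spec.segment_length is not None:
            return float(rng.uniform(*spec.segment_length))
        return float(rng.uniform(*spec.segment_length_factor)) * 2 * radius

    # root segment: centered on the volume, heading upward-ish so the tree
    # has room to grow
    segs: list[TreeSegment] = []
    for _ in range(200):
        d = _unit(np.array([rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4), 1.0]))
        length = draw_length(spec.radius_root)
        center = ext * (0.5 + 0.08 * rng.uniform(-1, 1, 3))
        frac = 0.5 if spec.n_bifurcations == 0 else 0.85
        start = center - frac * length * d
        end = start + length * d
        if inside(start, spec.radius_root) and inside(end, spec.radius_root):
            break
    else:
        raise ValueError("volume too small to fit the root segment")
    segs.append(TreeSegment(0, start, end, spec.radius_root, None))
    next_id = 1

    depth = {0: 0}
    leaves = [0]
    for _ in range(spec.n_bifurcations):
        placed = False
        # grow breadth-first-ish: split shallow leaves first so radii stay
        # comfortably above the rasterization limit over many bifurcations
        min_d = min(depth[l] for l in leaves)
        shallow = [l for l in leaves if depth[l] == min_d]
        deep = [l for l in leaves if depth[l] != min_d]
        order = list(rng.permutation(shallow)) + list(rng.permutation(deep))
        for leaf_id in order:
            parent = segs[leaf_id]
            r_child = parent.radius * spec.radius_decay
            for try_i in range(60):
                if try_i < 20:
                    az = rng.uniform(0, 2 * np.pi)
                else:
                    # steer back toward the volume center when free growth
                    # keeps leaving the bounds
                    u, v = _perp_basis(parent.direction)
                    cdir = ext * 0.5 - parent.end
                    az = float(np.arctan2(cdir @ v, cdir @ u)) + rng.uniform(-0.8, 0.8)
                pol1, pol2 = np.deg2rad(rng.uniform(20, 60, 2))
                d1 = _rotate_from(parent.direction, pol1, az)
                d2 = _rotate_from(parent.direction, pol2, az + np.pi + rng.uniform(-0.5, 0.5))
                l1, l2 = draw_length(r_child), draw_length(r_child)
                e1 = parent.end + l1 * d1
                e2 = parent.end + l2 * d2
                if not (inside(e1, r_child) and inside(e2, r_child)):
                    continue
                excl = {parent.id, parent.parent}
                if not (
                    clear_of_others(parent.end, e1, r_child, excl)
                    and clear_of_others(parent.end, e2, r_child, excl)
                ):
                    continue
                c1 = TreeSegment(next_id, parent.end.copy(), e1, r_child, parent.id)
                c2 = TreeSegment(next_id + 1, parent.end.copy(), e2, r_child, parent.id)
                segs.extend([c1, c2])
                leaves.remove(parent.id)
                leaves.extend([next_id, next_id + 1])
                depth[next_id] = depth[next_id + 1] = depth[parent.id] + 1
                next_id += 2
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ValueError(
                f"could not place bifurcation {len(segs)//2 + 1} within retry cap"
            )

    gt = GroundTruth(spec=spec, segments=segs)

    # stub injection (spurious branches for pruning tests): only on fully
    # internal segments, so every true leaf keeps its full proper length
    rng_s = np.random.default_rng(spec.rng_seed + 7919)
    leaf_ids = {x.id for x in gt.leaf_segments()}
    internal = [s for s in segs if s.id not in leaf_ids and s.parent is not None]
    for i in range(spec.stub_count):
        if not internal:
            break
        origin_seg = internal[int(rng_s.integers(0, len(internal)))]
        base = origin_seg.start + rng_s.uniform(0.35, 0.65) * (origin_seg.end - origin_seg.start)
        stub_len = spec.stub_length_factor * 2 * spec.stub_radius + origin_seg.radius
        for _ in range(40):
            d = _rotate_from(origin_seg.direction, np.deg2rad(rng_s.uniform(60, 90)),
                             rng_s.uniform(0, 2 * np.pi))
            tip = base + stub_len * d
            pad = 3 * max(spec.spacing)
            clear_of_stubs = all(
                min(
                    _point_segment_dist(base + t * (tip - base), st.start, st.end)
                    for t in np.linspace(0.0, 1.0, 12)
                )
                >= spec.stub_radius + st.radius + pad
                for st in gt.stubs
            )
            if (
                inside(tip, spec.stub_radius)
                and clear_of_others(base, tip, spec.stub_radius, {origin_seg.id}, pad=pad)
                and clear_of_stubs
            ):
                gt.stubs.append(
                    TreeSegment(1000 + i, base, tip, spec.stub_radius, origin_seg.id, True)
                )
                break

    gt.mask = _rasterize_mask(gt, spec, include_stubs=True)
    return gt


def _tube_mask_into(out: np.ndarray, seg: TreeSegment, spec: PhantomSpec, inner_frac=0.0):
    """OR the voxels within (inner_frac*r, r] of the segment axis into out."""
    sp = np.asarray(spec.spacing)
    r = seg.radius
    lo = np.maximum(np.floor((np.minimum(seg.start, seg.end) - r) / sp - 1), 0).astype(int)
    hi = np.minimum(
        np.ceil((np.maximum(seg.start, seg.end) + r) / sp + 1), np.asarray(spec.dims)
    ).astype(int)
    if np.any(lo >= hi):
        return
    ix, iy, iz = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = (np.stack([ix, iy, iz], axis=-1) + 0.5) * sp
    ab = seg.end - seg.start
    denom = max(float(ab @ ab), 1e-12)
    t = np.clip(((pts - seg.start) @ ab) / denom, 0.0, 1.0)
    closest = seg.start + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    sel = dist <= r
    if inner_frac > 0:
        sel &= dist > inner_frac * r
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sel


def _rasterize_mask(gt: GroundTruth, spec: PhantomSpec, include_stubs: bool) -> np.ndarray:
    mask = np.zeros(spec.dims, dtype=bool)
    for seg in gt.segments + (gt.stubs if include_stubs else []):
        _tube_mask_into(mask, seg, spec)
    return mask


def rasterize(gt: GroundTruth, spec: PhantomSpec | None = None) -> VoxelGrid:
    """Render the tree as an intensity volume (solid or hollow walls + noise)."""
    spec = spec or gt.spec
    full = _rasterize_mask(gt, spec, include_stubs=True)
    if spec.wall_mode == "hollow":
        lumen = np.zeros(spec.dims, dtype=bool)
        for seg in gt.segments + gt.stubs:
            inner = TreeSegment(seg.id, seg.start, seg.end,
                                seg.radius * (1 - spec.wall_thickness), seg.parent)
            _tube_mask_into(lumen, inner, spec)
        # cap terminal openings (solid ball at each tip) so the lumen is an
        # enclosed cavity, as in blind-ended stained vessels
        caps = np.zeros(spec.dims, dtype=bool)
        all_segs = gt.segments + gt.stubs
        parents = {s.parent for s in all_segs if s.parent is not None}
        for s in all_segs:
            tips = []
            if s.parent is None:
                tips.append(s.start)
            if s.id not in parents:
                tips.append(s.end)
            for tip in tips:
                ball = TreeSegment(-1, tip, tip + 1e-9 * s.direction, s.radius, None)
                _tube_mask_into(caps, ball, spec)
        bright = (full & ~lumen) | caps
    else:
        bright = full
    vol = np.where(bright, spec.fg_intensity, spec.bg_intensity).astype(np.float64)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed + 104729)
        vol += rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    dt = np.dtype(spec.dtype)
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        vol = np.clip(np.rint(vol), info.min, info.max)
    return VoxelGrid(vol.astype(dt), spec.spacing)


def make_seeds(
    gt: GroundTruth,
    n_fg_strokes: int | None = None,
    n_bg_points: int = 30,
    seed: int | None = None,
    margin_vox: float = 3.0,
    bg_grid: int | None = 12,
) -> SeedSet:
    """Deterministic seed annotation standing in for interactive labeling.

    Foreground strokes run along the true centerlines of the largest-radius
    segments (default: every segment, as an interactive user labels each
    vessel they want measured).  Background is labeled broadly: a jittered
    lattice with pitch ``bg_grid`` voxels plus ``n_bg_points`` random
    points, all at least ``margin_vox`` voxels away from the rendered mask;
    the broad coverage survives coarse-level seed scaling.
    """
    spec = gt.spec
    rng = np.random.default_rng(spec.rng_seed + 15013 if seed is None else seed)
    sp = np.asarray(spec.spacing)
    dims = np.asarray(spec.dims)

    fg: set = set()
    by_radius = sorted(gt.segments, key=lambda s: (-s.radius, s.id))
    n_strokes = len(by_radius) if n_fg_strokes is None else max(n_fg_strokes, 0)
    for seg in by_radius[:n_strokes]:
        n_pts = max(int(seg.length / (2 * sp.max())), 2)
        for t in np.linspace(0.15, 0.85, n_pts):
            p = seg.start + t * (seg.end - seg.start)
            v = tuple(np.clip((p / sp - 0.5).round().astype(int), 0, dims - 1))
            if gt.mask[v]:
                fg.add(v)

    dist_to_fg = ndi.distance_transform_edt(~gt.mask)
    far = dist_to_fg > margin_vox
    eligible = np.argwhere(far)
    if len(eligible) < n_bg_points:
        raise ValueError("not enough background space for seed placement")
    bg: set = set()
    if bg_grid:
        for base in np.ndindex(*(max(d // bg_grid, 1) for d in dims)):
            p = np.asarray(base) * bg_grid + bg_grid // 2
            p = np.clip(p + rng.integers(-2, 3, size=3), 0, dims - 1)
            if far[tuple(p)]:
                bg.add(tuple(int(c) for c in p))
    if n_bg_points > 0:
        pick = rng.choice(len(eligible), size=min(n_bg_points, len(eligible)), replace=False)
        bg |= {tuple(int(c) for c in eligible[i]) for i in sorted(pick)}
    return SeedSet(fg, bg - fg)


def branch_recall(gt: GroundTruth, vg, tol_vox: float = 2.0) -> float:
    """Fraction of true segments whose distal part is covered by the graph.

    A true segment counts as recovered when some extracted centerline point
    lies within ``max(radius, tol_vox * spacing)`` of the point 85% along
    its axis.
    """
    pts = (
        np.vstack([s.centerline for s in vg.segments])
        if vg.n_segments
        else np.zeros((0, 3))
    )
    tol_phys = tol_vox * max(gt.spec.spacing)
    hit = 0
    for s in gt.segments:
        probe = s.start + 0.85 * (s.end - s.start)
        tol = max(s.radius, tol_phys)
        if len(pts) and np.min(np.linalg.norm(pts - probe, axis=1)) <= tol:
            hit += 1
    return hit / max(len(gt.segments), 1)
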