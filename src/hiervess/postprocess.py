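"""Binary mask cleanup between segmentation and graph extraction.

Three steps, in the order they are meant to run: median surface smoothing,
removal of spurious foreground fragments, and filling of cavities
(background components fully enclosed by foreground — e.g. the vessel lumen
of hollow vessels, which must be solid before thinning).

Connected-component labeling is implemented as a two-pass brick-streaming
algorithm with a union-find over brick-border label equivalences, so the
peak memory is bounded by one brick row plus the label table; an in-memory
flood fill (scipy.ndimage.label) serves as its oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    26: ndi.generate_binary_structure(3, 3),
}


def median_smooth(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Majority filter over the cubic (2r+1)^3 neighborhood.

    Neighborhoods truncated at the volume edge use existing voxels only;
    ties go to foreground.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    k = 2 * radius + 1
    kernel = np.ones((k, k, k), dtype=np.int32)
    count = ndi.convolve(mask.astype(np.int32), kernel, mode="constant", cval=0)
    total = ndi.convolve(np.ones(mask.shape, dtype=np.int32), kernel, mode="constant", cval=0)
    return 2 * count >= total


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        root = x
        while self.parent.get(root, root) != root:
            root = self.parent[root]
        while self.parent.get(x, x) != x:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def connected_components(
    mask: np.ndarray, connectivity: int = 26, brick_size: int = 64
) -> tuple[np.ndarray, dict[int, int]]:
    """Two-pass out-of-core style connected-component labeling.

    Pass 1 labels each brick independently (offsetting labels so they are
    globally unique) and records label equivalences across brick borders by
    re-labeling the two-voxel-thick slabs that straddle every brick
    boundary plane.  Pass 2 relabels through the union-find and renumbers
    components 1..K in first-appearance order.

    Returns the label volume and a ``{label: voxel count}`` dictionary.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    struct = _STRUCTS[connectivity]
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int64)
    b = brick_size
    dims = mask.shape

    # pass 1: per-brick local labeling with global offsets
    next_label = 0
    for x0 in range(0, dims[0], b):
        for y0 in range(0, dims[1], b):
            for z0 in range(0, dims[2], b):
                sl = (
                    slice(x0, min(x0 + b, dims[0])),
                    slice(y0, min(y0 + b, dims[1])),
                    slice(z0, min(z0 + b, dims[2])),
                )
                loc, n = ndi.label(mask[sl], structure=struct)
                loc = loc.astype(np.int64)
                loc[loc > 0] += next_label
                labels[sl] = loc
                next_label += n

    # border equivalences: 2-thick slab across every brick boundary plane
    uf = _UnionFind()
    for axis in range(3):
        for cut in range(b, dims[axis], b):
            sl = [slice(None)] * 3
            sl[axis] = slice(cut - 1, cut + 1)
            slab_lab = labels[tuple(sl)]
            slab_cc, n = ndi.label(slab_lab > 0, structure=struct)
            for comp in range(1, n + 1):
                members = np.unique(slab_lab[slab_cc == comp])
                members = members[members > 0]
                for m in members[1:]:
                    uf.union(int(members[0]), int(m))

    # pass 2: resolve roots, renumber compactly, count sizes
    if next_label:
        root = np.arange(next_label + 1, dtype=np.int64)
        for lab in range(1, next_label + 1):
            root[lab] = uf.find(lab)
        remap = np.zeros(next_label + 1, dtype=np.int64)
        k = 0
        order = np.unique(root[1:])
        for r in order:
            k += 1
            remap[r] = k
        labels = remap[root[labels]]
    sizes = {
        int(lab): int(cnt)
        for lab, cnt in zip(*np.unique(labels[labels > 0], return_counts=True))
    }
    return labels, sizes


def remove_spurious_and_fill(
    mask: np.ndarray,
    min_fg_size: int | None = None,
    connectivity_fg: int = 26,
    connectivity_bg: int = 6,
) -> np.ndarray:
    """Delete small foreground fragments and fill enclosed cavities.

    ``min_fg_size=None`` keeps only the largest foreground component (one
    vascular tree); otherwise components below the size are removed.
    Background components with no voxel on the volume hull are cavities and
    are filled to foreground.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    lab, sizes = connected_components(mask, connectivity_fg)
    if sizes:
        if min_fg_size is None:
            keep = {max(sizes, key=lambda k: (sizes[k], -k))}
        else:
            keep = {k for k, v in sizes.items() if v >= min_fg_size}
        mask = np.isin(lab, sorted(keep))

    blab, _ = connected_components(~mask, connectivity_bg)
    hull_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            hull_labels.update(np.unique(blab[tuple(sl)]).tolist())
    hull_labels.discard(0)
    cavity = (blab > 0) & ~np.isin(blab, sorted(hull_labels))
    return mask | cavity
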