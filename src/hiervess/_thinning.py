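"""3D topology-preserving voxel thinning (Lee-style medial-axis skeleton).

Iterative parallel thinning in the 6-subiteration directional scheme of Lee,
Kashyap and Chu: in each pass, border points of one face direction (U, D, N,
S, E, W — a fixed published order, so the result is deterministic) are
collected as deletion candidates if they are simple and not line endpoints,
then deleted sequentially with a re-check so that simultaneous deletions
cannot break connectivity.

Point "simplicity" uses the standard local characterization (Malandain &
Bertrand): a foreground voxel is simple iff its 26-neighborhood contains
exactly one 26-connected foreground component, and the background of its
18-neighborhood contains exactly one 6-connected component that is
6-adjacent to the voxel.  Endpoints (exactly one foreground 26-neighbor)
and isolated voxels are never deleted, so each object retains a thin,
connected medial representative.

The inner loops are numba-compiled; the first call pays a compile cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# face directions in the fixed subiteration order: U, D, N, S, E, W
_DIRECTIONS = np.array(
    [
        [0, 0, 1],
        [0, 0, -1],
        [0, 1, 0],
        [0, -1, 0],
        [1, 0, 0],
        [-1, 0, 0],
    ],
    dtype=np.int64,
)

_OFF26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _neighborhood(img, x, y, z, out):
    """Copy the 3x3x3 neighborhood into a flat 27 array (center included)."""
    k = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                out[k] = img[x + dx, y + dy, z + dz]
                k += 1


@njit(cache=True)
def _n26_count(nb):
    c = 0
    for k in range(27):
        if k != 13 and nb[k] != 0:
            c += 1
    return c


@njit(cache=True)
def _is_simple(nb):
    """Simple-point test on a flat 27-neighborhood (center at index 13)."""
    # --- condition 1: exactly one 26-connected fg component in N26 ---
    labels = np.zeros(27, dtype=np.int8)
    ncomp = 0
    stack = np.empty(27, dtype=np.int8)
    for start in range(27):
        if start == 13 or nb[start] == 0 or labels[start] != 0:
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        top = 0
        stack[top] = start
        top += 1
        labels[start] = 1
        while top > 0:
            top -= 1
            k = stack[top]
            kx, ky, kz = k // 9 - 1, (k // 3) % 3 - 1, k % 3 - 1
            for m in range(27):
                if m == 13 or nb[m] == 0 or labels[m] != 0:
                    continue
                mx, my, mz = m // 9 - 1, (m // 3) % 3 - 1, m % 3 - 1
                if abs(mx - kx) <= 1 and abs(my - ky) <= 1 and abs(mz - kz) <= 1:
                    labels[m] = 1
                    stack[top] = m
                    top += 1
    if ncomp != 1:
        return False

    # --- condition 2: exactly one 6-connected bg component in N18 that is
    # 6-adjacent to the center ---
    labels[:] = 0
    ncomp = 0
    for start in range(27):
        if start == 13 or nb[start] != 0 or labels[start] != 0:
            continue
        sx, sy, sz = start // 9 - 1, (start // 3) % 3 - 1, start % 3 - 1
        if abs(sx) + abs(sy) + abs(sz) != 1:  # grow only from 6-neighbors
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        top = 0
        stack[top] = start
        top += 1
        labels[start] = 1
        while top > 0:
            top -= 1
            k = stack[top]
            kx, ky, kz = k // 9 - 1, (k // 3) % 3 - 1, k % 3 - 1
            for m in range(27):
                if m == 13 or nb[m] != 0 or labels[m] != 0:
                    continue
                mx, my, mz = m // 9 - 1, (m // 3) % 3 - 1, m % 3 - 1
                if abs(mx) + abs(my) + abs(mz) > 2:  # stay inside N18
                    continue
                if abs(mx - kx) + abs(my - ky) + abs(mz - kz) == 1:
                    labels[m] = 1
                    stack[top] = m
                    top += 1
    return ncomp == 1


@njit(cache=True)
def _thin_pass(img, direction, deleted):
    """One directional subiteration; returns number of deleted voxels."""
    dx, dy, dz = direction[0], direction[1], direction[2]
    nx, ny, nz = img.shape
    # collect candidates: border points of this direction, simple, not
    # endpoints (capped buffer; an overflow is caught by the next sweep)
    cap = 2_000_000
    cand = np.empty((cap, 3), dtype=np.int64)
    ncand = 0
    nb = np.empty(27, dtype=np.uint8)
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if img[x, y, z] == 0 or img[x + dx, y + dy, z + dz] != 0:
                    continue
                _neighborhood(img, x, y, z, nb)
                if _n26_count(nb) < 2:
                    continue  # endpoint or isolated: preserved
                if _is_simple(nb) and ncand < cap:
                    cand[ncand, 0] = x
                    cand[ncand, 1] = y
                    cand[ncand, 2] = z
                    ncand += 1
    # sequential re-checked deletion.  Two 26-adjacent voxels are never
    # deleted in the same pass: without this guard, deletions cascade along
    # 2-voxel-wide rods ("fuse burning") and can consume a whole straight
    # even-width tube; with it, per-pass deletions form an independent set
    # of simple points, which is topology-safe in any order.
    ndel = 0
    for i in range(ncand):
        x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
        blocked = False
        for dxx in range(-1, 2):
            for dyy in range(-1, 2):
                for dzz in range(-1, 2):
                    if deleted[x + dxx, y + dyy, z + dzz] != 0:
                        blocked = True
        if blocked:
            continue
        _neighborhood(img, x, y, z, nb)
        if _n26_count(nb) >= 2 and _is_simple(nb):
            img[x, y, z] = 0
            deleted[x, y, z] = 1
            ndel += 1
    return ndel


def lee_thinning(mask: np.ndarray) -> np.ndarray:
    """Thin a binary volume to a one-voxel-wide, topology-preserving skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    img = np.zeros(tuple(s + 2 for s in mask.shape), dtype=np.uint8)
    img[1:-1, 1:-1, 1:-1] = mask
    deleted = np.zeros_like(img)
    while True:
        ndel = 0
        for d in range(6):
            deleted[:] = 0
            ndel += _thin_pass(img, _DIRECTIONS[d], deleted)
        if ndel == 0:
            break
    return img[1:-1, 1:-1, 1:-1].astype(bool)
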