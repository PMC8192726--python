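"""Bricked octree level-of-detail pyramid with bounded-memory brick access.

The pyramid subdivides each resolution level into cubic bricks (default
32x32x32 voxels).  Level 0 is full resolution; each coarser level halves
every dimension (ceil division), a coarse voxel holding the arithmetic mean
of its up-to-2x2x2 children (cells truncated at the volume border average
only the children that exist).  Levels are added until the top level fits in
a single brick.

All brick access flows through an instrumented LRU cache so that volumes far
larger than main memory can be processed with a fixed brick budget; the
instrumentation (`CacheStats`) is what the out-of-core tests assert on.
Bricks are persisted in an HDF5 container, one chunked dataset per level,
chunk size equal to the brick size.
"""

from __future__ import annotations

import math
import os
import tempfile
from collections import OrderedDict
from dataclasses import dataclass
from itertools import product

import numpy as np
import h5py

from .volume import VoxelGrid


@dataclass(frozen=True)
class BrickIndex:
    """Address of one brick: resolution level plus brick-grid coordinates."""

    level: int
    bx: int
    by: int
    bz: int

    @property
    def coords(self) -> tuple[int, int, int]:
        return (self.bx, self.by, self.bz)


@dataclass
class CacheStats:
    """Instrumentation for the brick cache (out-of-core memory contract)."""

    resident: int = 0
    peak_resident: int = 0
    hits: int = 0
    misses: int = 0
    evictions: int = 0

    def reset_peak(self) -> None:
        self.peak_resident = self.resident


def downsample_block(children) -> float:
    """Mean of the 1-8 child voxel values of one coarse cell.

    Cells at the volume border may have fewer than 8 children; only existing
    children contribute (border cells are never darkened by padding).
    """
    vals = np.asarray(children, dtype=float).ravel()
    if vals.size == 0 or vals.size > 8:
        raise ValueError(f"expected 1-8 child values, got {vals.size}")
    return float(vals.mean())


def halfsample(a: np.ndarray) -> np.ndarray:
    """Downsample a 3D array by 2 per axis, averaging existing children only."""
    out_shape = tuple((s + 1) // 2 for s in a.shape)
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int32)
    for dx, dy, dz in product(range(2), repeat=3):
        sub = a[dx::2, dy::2, dz::2]
        sl = tuple(slice(0, s) for s in sub.shape)
        acc[sl] += sub
        cnt[sl] += 1
    return (acc / cnt).astype(np.float32)


def n_levels_for(dims, brick_size: int) -> int:
    """Number of pyramid levels until the top level fits in a single brick."""
    dims = tuple(int(d) for d in dims)
    n = 1
    while max(dims) > brick_size:
        dims = tuple((d + 1) // 2 for d in dims)
        n += 1
    return n


def level_dims(dims0, level: int) -> tuple[int, int, int]:
    d = tuple(int(x) for x in dims0)
    for _ in range(level):
        d = tuple((x + 1) // 2 for x in d)
    return d  # type: ignore[return-value]


class BrickStore:
    """HDF5-backed multi-level brick array with an instrumented LRU cache.

    One dataset per level, chunked by brick.  ``get``/``put`` move whole
    bricks through the cache; at most ``cache_budget`` decoded bricks are
    resident at any time.  Border bricks are stored zero-padded to the full
    brick shape; the valid extent is recoverable from the level dims.
    """

    def __init__(
        self,
        path: str | None,
        dims0,
        brick_size: int,
        n_levels: int,
        cache_budget: int = 64,
        dtype=np.float32,
        mode: str = "a",
    ) -> None:
        if brick_size < 8 or brick_size & (brick_size - 1):
            raise ValueError(f"brick_size must be a power of two >= 8, got {brick_size}")
        if cache_budget < 1:
            raise ValueError("cache_budget must be >= 1")
        self.brick_size = int(brick_size)
        self.dims0 = tuple(int(d) for d in dims0)
        self.n_levels = int(n_levels)
        self.cache_budget = int(cache_budget)
        self.dtype = np.dtype(dtype)
        self.stats = CacheStats()
        self._cache: OrderedDict[tuple, np.ndarray] = OrderedDict()
        self._own_tmp = path is None
        if path is None:
            fd, path = tempfile.mkstemp(suffix=".h5", prefix="hiervess_bricks_")
            os.close(fd)
            mode = "w"
        self.path = path
        # small HDF5 chunk cache: residency accounting lives in *our* cache
        self._f = h5py.File(path, mode, rdcc_nbytes=4 * 1024 * 1024)
        b = self.brick_size
        for lv in range(self.n_levels):
            name = f"level{lv}"
            if name not in self._f:
                nb = self.brick_counts(lv)
                shape = tuple(n * b for n in nb)
                self._f.create_dataset(
                    name, shape=shape, dtype=self.dtype, chunks=(b, b, b), fillvalue=0
                )

    # -- geometry -----------------------------------------------------------
    def dims(self, level: int) -> tuple[int, int, int]:
        return level_dims(self.dims0, level)

    def brick_counts(self, level: int) -> tuple[int, int, int]:
        b = self.brick_size
        return tuple(math.ceil(d / b) for d in self.dims(level))  # type: ignore[return-value]

    def valid_extent(self, idx: BrickIndex) -> tuple[int, int, int]:
        """Voxel counts of real (non-padding) data in this brick."""
        d = self.dims(idx.level)
        b = self.brick_size
        return tuple(
            min(b, d[a] - c * b) for a, c in enumerate(idx.coords)
        )  # type: ignore[return-value]

    def _check(self, idx: BrickIndex) -> None:
        if not 0 <= idx.level < self.n_levels:
            raise IndexError(f"level {idx.level} out of range [0, {self.n_levels})")
        nb = self.brick_counts(idx.level)
        if not all(0 <= c < n for c, n in zip(idx.coords, nb)):
            raise IndexError(f"brick {idx.coords} out of range {nb} at level {idx.level}")

    # -- brick access -------------------------------------------------------
    def get(self, idx: BrickIndex) -> np.ndarray:
        """Return the full (padded) brick; read-through LRU cached."""
        self._check(idx)
        key = (idx.level, *idx.coords)
        if key in self._cache:
            self._cache.move_to_end(key)
            self.stats.hits += 1
            return self._cache[key]
        self.stats.misses += 1
        b = self.brick_size
        lo = tuple(c * b for c in idx.coords)
        data = self._f[f"level{idx.level}"][
            lo[0] : lo[0] + b, lo[1] : lo[1] + b, lo[2] : lo[2] + b
        ]
        self._insert(key, data)
        return data

    def put(self, idx: BrickIndex, data: np.ndarray) -> None:
        """Write-through a full (padded) brick."""
        self._check(idx)
        b = self.brick_size
        if data.shape != (b, b, b):
            raise ValueError(f"brick shape {data.shape} != {(b, b, b)}")
        data = np.ascontiguousarray(data, dtype=self.dtype)
        lo = tuple(c * b for c in idx.coords)
        self._f[f"level{idx.level}"][
            lo[0] : lo[0] + b, lo[1] : lo[1] + b, lo[2] : lo[2] + b
        ] = data
        self._insert((idx.level, *idx.coords), data)

    def _insert(self, key, data) -> None:
        self._cache[key] = data
        self._cache.move_to_end(key)
        while len(self._cache) > self.cache_budget:
            self._cache.popitem(last=False)
            self.stats.evictions += 1
        self.stats.resident = len(self._cache)
        self.stats.peak_resident = max(self.stats.peak_resident, self.stats.resident)

    def read_region(self, level: int, lo, hi) -> np.ndarray:
        """Assemble an arbitrary [lo, hi) voxel box at a level, brick-wise.

        The box array itself is transient; the bricks it touches move through
        the bounded cache.
        """
        d = self.dims(level)
        lo = tuple(int(x) for x in lo)
        hi = tuple(int(x) for x in hi)
        if any(l < 0 or h > dd or l >= h for l, h, dd in zip(lo, hi, d)):
            raise IndexError(f"region {lo}..{hi} outside level dims {d}")
        b = self.brick_size
        out = np.empty(tuple(h - l for l, h in zip(lo, hi)), dtype=self.dtype)
        for cx in range(lo[0] // b, (hi[0] - 1) // b + 1):
            for cy in range(lo[1] // b, (hi[1] - 1) // b + 1):
                for cz in range(lo[2] // b, (hi[2] - 1) // b + 1):
                    brick = self.get(BrickIndex(level, cx, cy, cz))
                    blo = (cx * b, cy * b, cz * b)
                    slo = tuple(max(l, o) for l, o in zip(lo, blo))
                    shi = tuple(min(h, o + b) for h, o in zip(hi, blo))
                    src = tuple(
                        slice(a - o, c - o) for a, c, o in zip(slo, shi, blo)
                    )
                    dst = tuple(slice(a - l, c - l) for a, c, l in zip(slo, shi, lo))
                    out[dst] = brick[src]
        return out

    def write_region(self, level: int, lo, data: np.ndarray) -> None:
        """Write a voxel box at a level directly to backing storage."""
        lo = tuple(int(x) for x in lo)
        self._f[f"level{level}"][
            lo[0] : lo[0] + data.shape[0],
            lo[1] : lo[1] + data.shape[1],
            lo[2] : lo[2] + data.shape[2],
        ] = data
        # drop any stale cached bricks overlapping the region
        b = self.brick_size
        hi = tuple(l + s for l, s in zip(lo, data.shape))
        for cx in range(lo[0] // b, (hi[0] - 1) // b + 1):
            for cy in range(lo[1] // b, (hi[1] - 1) // b + 1):
                for cz in range(lo[2] // b, (hi[2] - 1) // b + 1):
                    self._cache.pop((level, cx, cy, cz), None)
        self.stats.resident = len(self._cache)

    def to_array(self, level: int) -> np.ndarray:
        """Materialize a whole level (small levels / test convenience)."""
        return self.read_region(level, (0, 0, 0), self.dims(level))

    def close(self) -> None:
        if self._f:
            self._f.close()
            self._f = None  # type: ignore[assignment]
        if self._own_tmp and os.path.exists(self.path):
            os.unlink(self.path)

    def __del__(self) -> None:  # best-effort cleanup of temp files
        try:
            self.close()
        except Exception:
            pass


class OctreePyramid:
    """Multi-resolution bricked image pyramid over a scalar volume.

    Intensities are stored as float32 at every level (exact for 8/16-bit
    input).  Global intensity min/max are recorded so that brick-local
    random-walker solves can normalize contrast consistently across bricks.
    """

    def __init__(self, store: BrickStore, spacing, intensity_min: float, intensity_max: float):
        self.store = store
        self.spacing = tuple(float(s) for s in spacing)
        self.intensity_min = float(intensity_min)
        self.intensity_max = float(intensity_max)

    # geometry passthroughs
    @property
    def brick_size(self) -> int:
        return self.store.brick_size

    @property
    def n_levels(self) -> int:
        return self.store.n_levels

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.store.dims0

    def level_dims(self, level: int) -> tuple[int, int, int]:
        return self.store.dims(level)

    def level_spacing(self, level: int) -> tuple[float, float, float]:
        return tuple(s * 2**level for s in self.spacing)  # type: ignore[return-value]

    def brick_counts(self, level: int) -> tuple[int, int, int]:
        return self.store.brick_counts(level)

    def get_brick(self, idx: BrickIndex) -> np.ndarray:
        return self.store.get(idx)

    @property
    def intensity_scale(self) -> float:
        return max(self.intensity_max - self.intensity_min, 1e-12)

    def save_attrs(self) -> None:
        f = self.store._f
        f.attrs["spacing_um"] = np.asarray(self.spacing)
        f.attrs["brick_size"] = self.store.brick_size
        f.attrs["n_levels"] = self.store.n_levels
        f.attrs["dims"] = np.asarray(self.store.dims0)
        f.attrs["intensity_min"] = self.intensity_min
        f.attrs["intensity_max"] = self.intensity_max

    @classmethod
    def open(cls, path: str, cache_budget: int = 64) -> "OctreePyramid":
        with h5py.File(path, "r") as f:
            dims0 = tuple(int(d) for d in f.attrs["dims"])
            bs = int(f.attrs["brick_size"])
            nl = int(f.attrs["n_levels"])
            spacing = tuple(float(s) for s in f.attrs["spacing_um"])
            imin = float(f.attrs["intensity_min"])
            imax = float(f.attrs["intensity_max"])
        store = BrickStore(path, dims0, bs, nl, cache_budget=cache_budget, mode="r+")
        return cls(store, spacing, imin, imax)

    def close(self) -> None:
        self.store.close()


def build_octree(
    grid: VoxelGrid,
    brick_size: int = 32,
    path: str | None = None,
    cache_budget: int = 64,
) -> OctreePyramid:
    """Build the LOD pyramid of a volume by repeated 2x2x2 mean-downsampling.

    Levels are added until the coarsest level occupies a single brick
    ("until only a single root block remains").  Border bricks are stored
    zero-padded; padding never contributes to the averages because
    downsampling runs on the unpadded level arrays.
    """
    a = np.asarray(grid.intensities, dtype=np.float32)
    if a.size == 0:
        raise ValueError("empty grid")
    nl = n_levels_for(a.shape, brick_size)
    store = BrickStore(path, a.shape, brick_size, nl, cache_budget=cache_budget)
    level = a
    for lv in range(nl):
        store.write_region(lv, (0, 0, 0), level)
        if lv < nl - 1:
            level = halfsample(level)
    pyr = OctreePyramid(
        store, grid.spacing, float(a.min()), float(a.max())
    )
    pyr.save_attrs()
    return pyr
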