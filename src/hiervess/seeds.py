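"""User seed annotations: hard foreground/background voxel labels.

Seeds come either as labeled voxel coordinates (CSV with columns
x,y,z,label) or as polyline strokes (JSON), which are rasterized to voxels
by 3D line stepping.  Coordinates are 0-based full-resolution (level-0)
voxel indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SeedSet:
    """Hard foreground/background seed voxels (level-0 coordinates)."""

    foreground: set = field(default_factory=set)
    background: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.foreground = {tuple(int(c) for c in p) for p in self.foreground}
        self.background = {tuple(int(c) for c in p) for p in self.background}
        overlap = self.foreground & self.background
        if overlap:
            raise ValueError(f"{len(overlap)} voxels labeled both fg and bg")

    def validate_inside(self, dims) -> None:
        for p in self.foreground | self.background:
            if not all(0 <= c < d for c, d in zip(p, dims)):
                raise ValueError(f"seed {p} outside volume dims {dims}")

    def __len__(self) -> int:
        return len(self.foreground) + len(self.background)

    def signature_in_box(self, lo, hi) -> tuple:
        """Canonical (hashable) content of seeds within [lo, hi) — used by
        the incremental-update reuse test."""
        fg = sorted(p for p in self.foreground if all(l <= c < h for c, l, h in zip(p, lo, hi)))
        bg = sorted(p for p in self.background if all(l <= c < h for c, l, h in zip(p, lo, hi)))
        return (tuple(fg), tuple(bg))


def rasterize_polyline(points) -> set:
    """Voxels visited by straight line stepping between consecutive points."""
    out: set = set()
    pts = [np.asarray(p, dtype=float) for p in points]
    if len(pts) == 1:
        out.add(tuple(int(round(c)) for c in pts[0]))
    for a, b in zip(pts[:-1], pts[1:]):
        n = int(np.ceil(np.abs(b - a).max())) + 1
        for t in np.linspace(0.0, 1.0, max(n, 2)):
            p = a + t * (b - a)
            out.add(tuple(int(round(c)) for c in p))
    return out


def read_seed_csv(path: str) -> SeedSet:
    """Read seeds from CSV with columns x, y, z, label in {fg, bg}."""
    df = pd.read_csv(path)
    need = {"x", "y", "z", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"seed CSV needs columns {sorted(need)}, has {list(df.columns)}")
    fg, bg = set(), set()
    for _, r in df.iterrows():
        p = (int(r.x), int(r.y), int(r.z))
        lab = str(r.label).strip().lower()
        if lab in ("fg", "foreground", "1"):
            fg.add(p)
        elif lab in ("bg", "background", "0"):
            bg.add(p)
        else:
            raise ValueError(f"unknown seed label {r.label!r}")
    return SeedSet(fg, bg)


def write_seed_csv(seeds: SeedSet, path: str) -> None:
    rows = [(x, y, z, "fg") for x, y, z in sorted(seeds.foreground)]
    rows += [(x, y, z, "bg") for x, y, z in sorted(seeds.background)]
    pd.DataFrame(rows, columns=["x", "y", "z", "label"]).to_csv(path, index=False)


def read_stroke_json(path: str) -> SeedSet:
    """Read polyline strokes: [{"label": "fg"|"bg", "points": [[x,y,z],...]}]."""
    with open(path) as f:
        strokes = json.load(f)
    fg, bg = set(), set()
    for s in strokes:
        vox = rasterize_polyline(s["points"])
        (fg if s["label"] == "fg" else bg).update(vox)
    return SeedSet(fg - bg, bg - fg) if fg & bg else SeedSet(fg, bg)


def scale_seeds_to_level(seeds: SeedSet, level: int) -> SeedSet:
    """Map level-0 seeds to a coarser level by integer-dividing by 2**level.

    Duplicates collapse; a coarse voxel receiving both labels is a conflict
    and is dropped from both sets.
    """
    if level == 0:
        return SeedSet(set(seeds.foreground), set(seeds.background))
    f = 2**level
    fg = {tuple(c // f for c in p) for p in seeds.foreground}
    bg = {tuple(c // f for c in p) for p in seeds.background}
    conflict = fg & bg
    return SeedSet(fg - conflict, bg - conflict)
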