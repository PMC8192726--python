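"""Morphometric read-outs from a pruned vessel graph.

Per-segment diameters (mean of the radius samples, times two) drive a
2-µm-bin frequency histogram and a three-way caliber classification —
small (d < 0.02 mm), medium (0.02 mm <= d < 0.1 mm), large (0.1 mm <= d) —
with per-class five-number summaries (median, quartiles, 1.5x-IQR whiskers)
of segment length and straightness.  Global totals: summed centerline
length, vessel volume by truncated-cone quadrature along the centerlines
(and, if masks are given, by voxel counting), and organ volume from an
organ mask.
"""

from __future__ import annotations

import numpy as np

from .graph import VesselGraph

SMALL_MAX_MM = 0.02
MEDIUM_MAX_MM = 0.1
CLASS_NAMES = ("small", "medium", "large")


def classify_by_diameter(d_mm: float) -> str:
    """Caliber class of a vessel diameter in millimeters.

    Boundaries are closed upward: d = 0.02 mm is medium, d = 0.1 mm large.
    """
    if d_mm < 0:
        raise ValueError(f"negative diameter {d_mm}")
    if d_mm < SMALL_MAX_MM:
        return "small"
    if d_mm < MEDIUM_MAX_MM:
        return "medium"
    return "large"


def diameter_histogram(diameters_um, bin_width_um: float = 2.0):
    """Left-closed right-open frequency bins from 0; counts conserve n.

    Returns ``(edges, counts)`` with ``edges`` of length ``len(counts)+1``.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(list(diameters_um), dtype=float)
    if d.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts = np.bincount(np.floor(d / bin_width_um).astype(int), minlength=n_bins)
    return edges, counts


def five_number(values) -> dict:
    """Median, quartiles and 1.5x-IQR whiskers (clipped to the data range)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = float(v[v >= q1 - 1.5 * iqr].min())
    hi = float(v[v <= q3 + 1.5 * iqr].max())
    return {
        "n": int(v.size), "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": lo, "whisker_high": hi,
    }


def summarize(
    vg: VesselGraph,
    organ_mask=None,
    vessel_mask=None,
    spacing=(1.0, 1.0, 1.0),
    bin_width_um: float = 2.0,
) -> dict:
    """Full morphometric report of a pruned vessel graph.

    Lengths in the report are millimeters, volumes cubic millimeters,
    histogram bins micrometers.  ``organ_mask``/``vessel_mask`` (optional
    binary volumes at the given spacing) add voxel-counting volumes.
    """
    segs = vg.segments
    diam_um = [s.avg_diameter for s in segs]
    edges, counts = diameter_histogram(diam_um, bin_width_um)

    per_class: dict[str, dict] = {}
    for cname in CLASS_NAMES:
        sel = [s for s in segs if classify_by_diameter(s.avg_diameter / 1000.0) == cname]
        per_class[cname] = {
            "n_segments": len(sel),
            "length_mm": five_number([s.length / 1000.0 for s in sel]),
            "straightness": five_number([s.straightness for s in sel]),
        }

    voxel_vol_um3 = float(np.prod(spacing))
    report = {
        "n_nodes": vg.n_nodes,
        "n_segments": len(segs),
        "total_length_mm": vg.total_length() / 1e3,
        "total_vessel_volume_mm3": vg.total_volume() / 1e9,
        "diameter_histogram": {
            "bin_width_um": bin_width_um,
            "edges_um": edges.tolist(),
            "counts": counts.tolist(),
        },
        "classes": per_class,
    }
    if vessel_mask is not None:
        report["vessel_volume_voxelcount_mm3"] = (
            float(np.count_nonzero(vessel_mask)) * voxel_vol_um3 / 1e9
        )
    if organ_mask is not None:
        report["organ_volume_mm3"] = (
            float(np.count_nonzero(organ_mask)) * voxel_vol_um3 / 1e9
        )
    return report


def plot_report(report: dict, outdir: str) -> None:
    """Diameter histogram and per-class length/straightness box plots."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    h = report["diameter_histogram"]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    edges = np.asarray(h["edges_um"])
    ax.bar(edges[:-1], h["counts"], width=h["bin_width_um"], align="edge",
           color="#4878a8", edgecolor="none")
    ax.set_xlabel("vessel diameter d (µm)")
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "diameter_histogram.png"), dpi=150)
    plt.close(fig)

    for metric, ylab in (("length_mm", "segment length (mm)"),
                         ("straightness", "straightness")):
        stats = []
        for cname in CLASS_NAMES:
            s = report["classes"][cname][metric]
            if s["n"]:
                stats.append({
                    "label": cname, "med": s["median"], "q1": s["q1"], "q3": s["q3"],
                    "whislo": s["whisker_low"], "whishi": s["whisker_high"], "fliers": [],
                })
        fig, ax = plt.subplots(figsize=(4, 3.2))
        if stats:
            ax.bxp(stats, showfliers=False)
        ax.set_ylabel(ylab)
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"{metric}_by_class.png"), dpi=150)
        plt.close(fig)
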