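"""Minimal QC rendering: detected centroids over the projection."""

from __future__ import annotations

import numpy as np


def qc_overlay(stack, particles, roi, path) -> None:
    """Save a PNG of the max projection with ROI outline and detections.

    Retained particles are drawn as circles, discarded doublets as crosses.
    This is a quick sanity check, not a publication figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = stack.voxels.max(axis=0)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(proj, cmap="gray", interpolation="nearest")
    plane = roi.plane(0)
    ax.contour(plane, levels=[0.5], colors="cyan", linewidths=0.8)
    kept = [p for p in particles.particles if p.kept_after_dedup]
    dropped = [p for p in particles.particles if not p.kept_after_dedup]
    if kept:
        pts = np.array([p.centroid for p in kept])
        ax.scatter(pts[:, 1], pts[:, 0], s=40, facecolors="none",
                   edgecolors="yellow", linewidths=0.8, label="retained")
    if dropped:
        pts = np.array([p.centroid for p in dropped])
        ax.scatter(pts[:, 1], pts[:, 0], s=14, marker="x", c="red",
                   linewidths=0.6, label="doublet (discarded)")
    if kept or dropped:
        ax.legend(loc="lower right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
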