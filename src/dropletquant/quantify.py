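"""Per-brain summary statistics and control-normalized group comparisons.

The per-brain quantities mirror what is reported for lipid-droplet screens:
particle count, density (count per ROI area), total and mean particle
surface, and the circularity distribution.  Because "surface" of a droplet
population can mean either the summed or the per-droplet mean cross-section,
both are reported.

Group results are expressed as fold changes over the control-group mean,
so control brains average to 1 by construction.  No hypothesis testing
happens here; the tables are designed to feed external statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import NormalizationError

__all__ = ["SummaryStats", "GroupComparison", "circularity", "summarize", "fold_change"]


def circularity(area: float, perimeter: float) -> float:
    """Shape descriptor ``4πA/P²``, clamped to 1.

    1 for a perfect disc, lower for irregular shapes.  A zero perimeter
    (degenerate single-pixel object under some estimators) returns 1 by
    convention.
    """
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


@dataclass
class SummaryStats:
    """Per-brain quantities derived from the deduplicated particle set."""

    brain_id: str
    n_particles: int
    density_per_px2: float
    density_per_um2: Optional[float]
    total_surface_px2: float
    total_surface_um2: Optional[float]
    mean_surface_px2: float
    circularity_mean: Optional[float]
    circularity_quartiles: Optional[tuple]
    per_slice_counts: List[int] = field(default_factory=list)

    def metric(self, name: str) -> float:
        """Look up a scalar metric by name (for fold-change tables)."""
        value = getattr(self, name)
        if value is None:
            raise KeyError(f"metric {name!r} unavailable for {self.brain_id}")
        return float(value)

    def to_dict(self) -> dict:
        q = self.circularity_quartiles
        return {
            "brain_id": self.brain_id,
            "n_particles": self.n_particles,
            "density_per_px2": self.density_per_px2,
            "density_per_um2": self.density_per_um2,
            "total_surface_px2": self.total_surface_px2,
            "total_surface_um2": self.total_surface_um2,
            "mean_surface_px2": self.mean_surface_px2,
            "circularity_mean": self.circularity_mean,
            "circularity_q25": q[0] if q else None,
            "circularity_q50": q[1] if q else None,
            "circularity_q75": q[2] if q else None,
        }


@dataclass
class GroupComparison:
    control_label: str
    test_label: str
    metric: str
    control_mean: float
    fold_changes: Dict[str, List[float]]  # label -> per-brain fold changes


def summarize(
    particle_set,
    roi,
    pixel_size_xy: Optional[float] = None,
    n_slices: Optional[int] = None,
) -> SummaryStats:
    """Summarize the retained (post-dedup) particles of one brain.

    ``roi`` may be an :class:`~dropletquant.stack_io.ROIMask` or a
    precomputed area dict from :func:`~dropletquant.roi.roi_area`.
    An empty particle set yields zero counts/surfaces and NA circularity.
    """
    from .roi import roi_area  # local import to keep module layering acyclic

    area = roi if isinstance(roi, dict) else roi_area(roi, pixel_size_xy)
    total_px = area["total_px"]
    if total_px <= 0:
        raise ValueError("ROI area is zero; density undefined")

    kept = particle_set.kept()
    n = len(kept)
    areas = np.array([p.pixel_count for p in kept], dtype=float)
    circs = np.array([p.circularity for p in kept], dtype=float)
    total_surface = float(areas.sum()) if n else 0.0

    if n_slices is None:
        n_slices = 1 + max((p.slice_index for p in kept), default=0)
    counts = [0] * n_slices
    for p in kept:
        counts[p.slice_index] += 1

    um2 = pixel_size_xy**2 if pixel_size_xy is not None else None
    return SummaryStats(
        brain_id=particle_set.brain_id,
        n_particles=n,
        density_per_px2=n / total_px,
        density_per_um2=(n / (total_px * um2)) if um2 else None,
        total_surface_px2=total_surface,
        total_surface_um2=(total_surface * um2) if um2 else None,
        mean_surface_px2=(total_surface / n) if n else 0.0,
        circularity_mean=float(circs.mean()) if n else None,
        circularity_quartiles=(
            tuple(float(q) for q in np.percentile(circs, [25, 50, 75])) if n else None
        ),
        per_slice_counts=counts,
    )


def fold_change(
    group: Sequence[SummaryStats],
    control: Sequence[SummaryStats],
    metric: str,
    control_label: str = "control",
    test_label: str = "test",
) -> GroupComparison:
    """Normalize a metric by the control-group mean.

    Every brain's value is divided by the mean of the control brains, so the
    control fold changes average to exactly 1.  Raises
    :class:`~dropletquant.errors.NormalizationError` when the control group
    is empty or its mean is zero.
    """
    if not control:
        raise NormalizationError("control group is empty")
    ctrl_vals = [s.metric(metric) for s in control]
    ctrl_mean = float(np.mean(ctrl_vals))
    if ctrl_mean == 0:
        raise NormalizationError(f"control mean of {metric!r} is zero")
    return GroupComparison(
        control_label=control_label,
        test_label=test_label,
        metric=metric,
        control_mean=ctrl_mean,
        fold_changes={
            control_label: [v / ctrl_mean for v in ctrl_vals],
            test_label: [s.metric(metric) / ctrl_mean for s in group],
        },
    )
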