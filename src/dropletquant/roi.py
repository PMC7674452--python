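"""Automatic delineation of the brain/tissue region of interest.

A whole-mount brain is a single bright region on a dark background, so the
ROI is recovered from the maximum-intensity projection of the stack:
project, smooth, threshold globally, close, fill holes, and keep the
largest connected component.  The mask is computed once per stack and
shared across slices — the anatomical region is stable over a typical
12-slice acquisition and a per-slice mask would flicker.

The triangle method is the default split for tissue vs. background: that
histogram is unimodal and skewed, where triangle is robust.  Max-entropy
thresholding is reserved for particle detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label

from .errors import DelineationError
from .stack_io import ImageStack, ROIMask

__all__ = ["RoiParams", "delineate_roi", "roi_area"]

logger = logging.getLogger(__name__)


@dataclass
class RoiParams:
    """Parameters of the projection→smooth→threshold→largest-component recipe.

    ``method`` is ``"triangle"``, ``"otsu"``, or ``"fixed:<value>"`` for an
    absolute intensity cutoff.  ``closing_radius`` sets the structuring
    element of the binary closing (px).  When ``fallback`` is true an empty
    mask degrades to a full-frame mask instead of raising.

    ``clip_percentile`` caps projection intensities at that percentile
    before the threshold is computed (the threshold is still applied to the
    uncapped image).  Droplets are sparse but can be an order of magnitude
    brighter than tissue; without the cap they drag a histogram-shape
    threshold above the tissue level and delineation collapses onto the
    brightest punctum.  ``None`` disables the cap.
    """

    sigma: float = 2.0
    method: str = "triangle"
    closing_radius: int = 5
    fallback: bool = True
    clip_percentile: Optional[float] = 99.5


def _threshold(projection: np.ndarray, method: str) -> float:
    if method == "triangle":
        return float(threshold_triangle(projection))
    if method == "otsu":
        return float(threshold_otsu(projection))
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    raise ValueError(f"unknown ROI threshold method {method!r}")


def delineate_roi(stack: ImageStack, params: Optional[RoiParams] = None) -> ROIMask:
    """Compute the tissue mask for ``stack``.

    Returns a 3-D :class:`ROIMask` with ``origin="auto"``, or a full-frame
    mask with ``origin="full-frame"`` when delineation finds nothing and
    ``params.fallback`` is enabled.
    """
    params = params or RoiParams()
    projection = stack.voxels.max(axis=0).astype(np.float64)
    smoothed = ndimage.gaussian_filter(projection, sigma=params.sigma, mode="reflect")

    for_threshold = smoothed
    if params.clip_percentile is not None:
        cap = np.percentile(smoothed, params.clip_percentile)
        for_threshold = np.minimum(smoothed, cap)

    try:
        t = _threshold(for_threshold, params.method)
        binary = smoothed > t
    except Exception:
        binary = np.zeros(projection.shape, dtype=bool)

    if binary.any():
        r = params.closing_radius
        if r > 0:
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            selem = (yy**2 + xx**2) <= r**2
            binary = ndimage.binary_closing(binary, structure=selem)
        binary = ndimage.binary_fill_holes(binary)
        labels, n = label(binary, connectivity=2, return_num=True)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            binary = labels == sizes.argmax()

    if not binary.any():
        if not params.fallback:
            raise DelineationError(
                "automatic ROI delineation produced an empty mask"
            )
        logger.warning("ROI delineation empty; falling back to full frame")
        return ROIMask(
            mask=np.ones(projection.shape, dtype=bool), origin="full-frame"
        ).broadcast(stack.n_slices)

    return ROIMask(mask=binary, origin="auto").broadcast(stack.n_slices)


def roi_area(mask: ROIMask, pixel_size_xy: Optional[float] = None) -> dict:
    """Per-slice and total true-pixel counts, with µm² when calibrated."""
    m = mask.mask if mask.mask.ndim == 3 else mask.mask[None]
    per_slice = m.sum(axis=(1, 2)).astype(int)
    out = {
        "per_slice_px": per_slice.tolist(),
        "total_px": int(per_slice.sum()),
    }
    if pixel_size_xy is not None:
        f = pixel_size_xy**2
        out["per_slice_um2"] = [float(c * f) for c in per_slice]
        out["total_um2"] = float(per_slice.sum() * f)
    return out
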