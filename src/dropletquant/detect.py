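"""Iterative brightest-particle detection with max-entropy thresholding.

Each slice is processed independently.  A working copy of the slice is
smoothed with a Gaussian, thresholded with the Kapur–Sahoo–Wong
maximum-entropy criterion on the within-ROI histogram, and the resulting
connected components are measured and then erased from the working copy.
Because erasing the brightest particles reshapes the histogram, the next
iteration settles on a lower threshold and surfaces dimmer particles.

Intensity statistics are always measured on the original, unblurred slice:
the smoothed image exists only to stabilise detection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .errors import DegenerateHistogramError
from .quantify import circularity
from .stack_io import ImageStack, ROIMask

__all__ = [
    "Particle",
    "ParticleSet",
    "DetectConfig",
    "max_entropy_threshold",
    "smooth",
    "extract_particles",
    "erase",
    "iterative_detect",
]


@dataclass
class Particle:
    """One detected 2-D object on a single slice.

    ``centroid`` is (y, x) in pixels, 0-based.  ``pixels`` holds the
    component's (y, x) coordinates.  ``iteration`` records on which pass of
    the iterative detector the particle surfaced (1 = brightest pass).
    """

    slice_index: int
    centroid: Tuple[float, float]
    pixel_count: int
    perimeter: float
    circularity: float
    mean_intensity: float
    max_intensity: float
    iteration: int
    pixels: np.ndarray
    kept_after_dedup: bool = True


@dataclass
class ParticleSet:
    """All particles of one brain, with the per-iteration threshold log."""

    brain_id: str
    particles: List[Particle] = field(default_factory=list)
    threshold_log: List[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def kept(self) -> List[Particle]:
        return [p for p in self.particles if p.kept_after_dedup]

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class DetectConfig:
    """Tunable parameters of the iterative detector.

    sigma
        Gaussian blur radius (px) applied to the detection copy.
    max_iterations
        Number of detect–erase passes per slice (early stop on empty pass).
    min_area, max_area
        Component size bounds in pixels.
    min_circularity
        Components below this 4πA/P² value are dropped (0 = report only).
    erase_fill
        Value written over detected pixels: the per-slice background median
        inside the ROI, or zero.
    erase_margin
        Radius (px) of the exclusion zone around erased particles in later
        iterations.  Erasing a bright particle leaves its blurred skirt in
        place, and once the threshold drops that skirt re-surfaces as a
        spurious dim ring; barring a small dilated margin around erased
        pixels suppresses it.  Only the re-detection mask is dilated — the
        erase operation itself touches exactly the particle's pixels.
        The default of 4 px covers the skirt of a particle ~100× brighter
        than the read noise under a ~1 px PSF (the skirt of a blurred disc
        falls below noise about 3.2 PSF widths beyond its thresholded core).
    containment
        "centroid" keeps a component whose centroid falls inside the ROI;
        "full" requires every pixel inside.
    noise_floor_k
        Stop iterating on a slice once the max-entropy threshold falls to or
        below ``median + k·(1.4826·MAD)`` of the smoothed within-ROI signal.
        After the real particles are erased the entropy criterion happily
        splits pure noise; this rule ends the loop there.  0 disables.
    """

    sigma: float = 1.0
    max_iterations: int = 3
    min_area: int = 4
    max_area: int = 10_000
    min_circularity: float = 0.0
    erase_fill: str = "background-median"
    erase_margin: int = 4
    histogram_bins: int = 256
    containment: str = "centroid"
    noise_floor_k: float = 3.0

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.erase_margin < 0:
            raise ValueError("erase_margin must be >= 0")
        if self.erase_fill not in ("background-median", "zero"):
            raise ValueError(f"unknown erase_fill {self.erase_fill!r}")
        if self.containment not in ("centroid", "full"):
            raise ValueError(f"unknown containment {self.containment!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def max_entropy_threshold(histogram: Sequence[int]) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold of a count histogram.

    Returns the bin index ``t`` maximizing ``H_bg(t) + H_fg(t)`` where the
    background class is bins ``0..t`` and the foreground class is bins
    ``t+1..B-1``; class probabilities are renormalized within each class and
    ``0·ln 0 ≡ 0``.  Thresholds leaving either class empty are excluded.
    Ties are broken toward the smallest ``t`` (inclusive foreground).
    Foreground pixels are those with bin index strictly greater than ``t``.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or len(hist) < 2:
        raise ValueError("histogram must be a 1-D vector of >= 2 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated bins"
        )
    total = hist.sum()
    p = hist / total
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])

    P1 = np.cumsum(p)  # background mass up to and including t
    S1 = np.cumsum(plogp)
    # suffix sums, not 1 - cumsum: rounding residue in the complement can
    # make an empty foreground class look admissible
    P2 = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])  # mass of bins > t
    S2 = np.concatenate([np.cumsum(plogp[::-1])[::-1][1:], [0.0]])

    with np.errstate(divide="ignore", invalid="ignore"):
        h_bg = -S1 / P1 + np.log(P1)
        h_fg = -S2 / P2 + np.log(P2)
    crit = h_bg + h_fg
    # each class must contain at least one populated bin
    has_bg = np.cumsum(nz) > 0
    has_fg = np.concatenate([(np.cumsum(nz[::-1])[::-1] > 0)[1:], [False]])
    crit[~(has_bg & has_fg)] = -np.inf
    # smallest argmax: np.argmax returns the first maximal index
    t = int(np.argmax(crit))
    if not np.isfinite(crit[t]):
        raise DegenerateHistogramError("no admissible threshold")
    return t


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with reflecting boundary; ``sigma == 0`` is identity."""
    img = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")


def binned_histogram(
    image: np.ndarray, roi_plane: np.ndarray, bins: int = 256
) -> Tuple[np.ndarray, np.ndarray, Tuple[float, float]]:
    """Bin an image into ``bins`` levels spanning its within-ROI range.

    Returns the per-pixel bin-index image, the within-ROI histogram, and
    the (min, max) range used.  Raises
    :class:`~dropletquant.errors.DegenerateHistogramError` on a flat ROI.
    """
    vals = image[roi_plane]
    if vals.size == 0:
        raise DegenerateHistogramError("ROI is empty on this slice")
    mn = float(vals.min())
    mx = float(vals.max())
    if mx <= mn:
        raise DegenerateHistogramError("slice is constant within the ROI")
    idx = np.floor((image - mn) / (mx - mn) * bins).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    hist = np.bincount(idx[roi_plane], minlength=bins)[:bins]
    return idx, hist, (mn, mx)


def _centroid_inside(roi_plane: np.ndarray, cy: float, cx: float) -> bool:
    iy = min(max(int(cy + 0.5), 0), roi_plane.shape[0] - 1)
    ix = min(max(int(cx + 0.5), 0), roi_plane.shape[1] - 1)
    return bool(roi_plane[iy, ix])


def extract_particles(
    binary: np.ndarray,
    original: np.ndarray,
    roi_plane: np.ndarray,
    cfg: DetectConfig,
    z: int,
    iteration: int,
) -> List[Particle]:
    """Measure the 8-connected components of ``binary`` that pass filters.

    A component is kept iff it satisfies the ROI containment rule, its area
    lies in ``[min_area, max_area]``, and its circularity is at least
    ``min_circularity``.  Intensities come from ``original``.
    """
    labels = label(binary, connectivity=2)
    out: List[Particle] = []
    for region in regionprops(labels, intensity_image=original):
        area = int(region.area)
        if not (cfg.min_area <= area <= cfg.max_area):
            continue
        cy, cx = region.centroid
        if cfg.containment == "centroid":
            if not _centroid_inside(roi_plane, cy, cx):
                continue
        else:
            coords = region.coords
            if not roi_plane[coords[:, 0], coords[:, 1]].all():
                continue
        perim = float(region.perimeter)
        circ = circularity(area, perim)
        if circ < cfg.min_circularity:
            continue
        out.append(
            Particle(
                slice_index=z,
                centroid=(float(cy), float(cx)),
                pixel_count=area,
                perimeter=perim,
                circularity=circ,
                mean_intensity=float(region.intensity_mean),
                max_intensity=float(region.intensity_max),
                iteration=iteration,
                pixels=region.coords.copy(),
            )
        )
    return out


def erase(
    working: np.ndarray, particles: List[Particle], fill_value: float
) -> np.ndarray:
    """Set every pixel of every particle to ``fill_value`` (in place)."""
    for p in particles:
        working[p.pixels[:, 0], p.pixels[:, 1]] = fill_value
    return working


def iterative_detect(
    stack: ImageStack,
    roi: ROIMask,
    cfg: Optional[DetectConfig] = None,
    brain_id: str = "",
) -> ParticleSet:
    """Run the detect–measure–erase loop over every slice of a stack.

    Per slice: smooth a working copy, max-entropy threshold its within-ROI
    histogram, extract and measure components, erase them from the working
    copy, repeat up to ``cfg.max_iterations`` times, stopping early when a
    pass finds nothing or the histogram degenerates.  Previously erased
    pixels are barred from later detections, so particle pixel sets are
    pairwise disjoint within a slice.  The process is fully deterministic.
    """
    cfg = cfg or DetectConfig()
    roi = roi.broadcast(stack.n_slices)
    roi.validate_against(stack)
    selem = None
    if cfg.erase_margin > 0:
        m = cfg.erase_margin
        yy, xx = np.mgrid[-m : m + 1, -m : m + 1]
        selem = (yy**2 + xx**2) <= m**2
    result = ParticleSet(
        brain_id=brain_id or stack.source_path or "stack",
        config=cfg.to_dict(),
    )

    for z in range(stack.n_slices):
        original = stack.voxels[z]
        roi_plane = roi.plane(z)
        if not roi_plane.any():
            continue
        if cfg.erase_fill == "background-median":
            fill = float(np.median(original[roi_plane]))
        else:
            fill = 0.0
        working = original.astype(np.float64)
        erased = np.zeros(original.shape, dtype=bool)
        prev_t_value = np.inf

        for k in range(1, cfg.max_iterations + 1):
            detection = smooth(working, cfg.sigma)
            try:
                _, hist, (mn, mx) = binned_histogram(
                    detection, roi_plane, cfg.histogram_bins
                )
                t = max_entropy_threshold(hist)
            except DegenerateHistogramError as exc:
                result.threshold_log.append(
                    {"slice": z, "iteration": k, "degenerate": str(exc)}
                )
                break
            # clamp: each pass targets dimmer particles than the last, so a
            # recomputed threshold above the previous one (a re-binning
            # artifact of the shrunken range) is pulled back down
            t_value = min(
                mn + (t + 1) * (mx - mn) / cfg.histogram_bins, prev_t_value
            )
            prev_t_value = t_value
            if cfg.noise_floor_k > 0:
                vals = detection[roi_plane]
                med = float(np.median(vals))
                mad = float(np.median(np.abs(vals - med)))
                floor = med + cfg.noise_floor_k * 1.4826 * mad
                if t_value <= floor:
                    result.threshold_log.append(
                        {
                            "slice": z,
                            "iteration": k,
                            "threshold_bin": t,
                            "threshold_value": t_value,
                            "stopped": "below-noise-floor",
                            "noise_floor": floor,
                        }
                    )
                    break
            binary = detection >= t_value  # == (bin index > t) when unclamped
            if erased.any():
                barrier = (
                    ndimage.binary_dilation(erased, structure=selem)
                    if selem is not None
                    else erased
                )
                binary &= ~barrier
            found = extract_particles(binary, original, roi_plane, cfg, z, k)
            result.threshold_log.append(
                {
                    "slice": z,
                    "iteration": k,
                    "threshold_bin": t,
                    "threshold_value": t_value,
                    "n_particles": len(found),
                }
            )
            if not found:
                break
            result.particles.extend(found)
            erase(working, found, fill)
            for p in found:
                erased[p.pixels[:, 0], p.pixels[:, 1]] = True

    return result
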