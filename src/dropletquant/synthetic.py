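"""Synthetic confocal-like stacks with known planted droplets.

The generator emulates the features of a BODIPY-stained whole-mount brain
that the detector relies on: a dark exterior with additive read noise, a
single bright contiguous tissue disc, and quasi-spherical droplets whose
peak brightness spans a wide (log-uniform) range — so one thresholding pass
catches only the bright ones and the iterative passes have work to do.
Each droplet intersects several consecutive slices with its cross-section
shrinking away from the central slice, which exercises doublet removal.

Everything is driven by a single integer seed; identical specs and seeds
produce bitwise-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .errors import SpecError
from .stack_io import ImageStack

__all__ = [
    "SyntheticSpec",
    "DropletRecord",
    "GroundTruth",
    "EvalMetrics",
    "generate_stack",
    "match_and_score",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic stack.

    Defaults are the standard benchmark: 60 droplets of radius 2–6 px over
    12 slices of 512×512, droplet peak amplitudes 3–20× the background level
    (log-uniform), Gaussian read noise with sd = background / 5.
    ``droplet_intensity_range`` is expressed in multiples of ``background``
    and applied as amplitude above the local tissue level.
    """

    shape: Tuple[int, int, int] = (12, 512, 512)
    tissue_center: Tuple[float, float] = (256.0, 256.0)
    tissue_radius: float = 200.0
    tissue_intensity: float = 30.0
    background: float = 10.0
    n_droplets: int = 60
    droplet_radius_range: Tuple[float, float] = (2.0, 6.0)
    droplet_intensity_range: Tuple[float, float] = (3.0, 20.0)
    z_extent_range: Tuple[int, int] = (3, 5)
    noise_sd: Optional[float] = None  # None -> background / 5
    poisson: bool = False
    psf_sigma: float = 1.0
    bit_depth: int = 8
    seed: int = 0
    min_separation: float = 6.0  # gap added between droplet rims

    def __post_init__(self) -> None:
        if self.n_droplets < 0:
            raise SpecError("n_droplets must be >= 0")
        if self.droplet_intensity_range[0] < 1:
            raise SpecError("droplet intensities must exceed the background")
        if self.tissue_intensity <= self.background:
            raise SpecError("tissue must be brighter than the background")
        rmax = self.droplet_radius_range[1]
        if rmax + 2 * self.psf_sigma >= self.tissue_radius:
            raise SpecError("droplets cannot fit inside the tissue disc")

    @property
    def effective_noise_sd(self) -> float:
        return self.background / 5.0 if self.noise_sd is None else self.noise_sd

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shape", "tissue_center", "droplet_radius_range",
                    "droplet_intensity_range", "z_extent_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DropletRecord:
    """Ground-truth record of one planted droplet."""

    droplet_id: int
    z_center: int
    center: Tuple[float, float]  # (y, x)
    radius: float
    peak_intensity: float  # amplitude above tissue level
    slices: List[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    records: List[DropletRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    f1: float
    mean_abs_size_error_px2: Optional[float]
    decile_recall: List[float]
    n_detected: int
    n_truth: int
    n_matched: int


def _sample_droplets(spec: SyntheticSpec, rng: np.random.Generator) -> List[DropletRecord]:
    nz = spec.shape[0]
    cy, cx = spec.tissue_center
    records: List[DropletRecord] = []
    lo_a = spec.droplet_intensity_range[0] * spec.background
    hi_a = spec.droplet_intensity_range[1] * spec.background
    for i in range(spec.n_droplets):
        r = rng.uniform(*spec.droplet_radius_range)
        amplitude = math.exp(rng.uniform(math.log(lo_a), math.log(hi_a)))
        e = int(rng.integers(spec.z_extent_range[0], spec.z_extent_range[1] + 1))
        e = min(e, nz)
        z_lo_off, z_hi_off = (e - 1) // 2, e // 2
        z0 = int(rng.integers(z_lo_off, nz - z_hi_off))
        max_off = spec.tissue_radius - r - 2 * spec.psf_sigma - 1
        placed = False
        for _ in range(2000):
            ang = rng.uniform(0, 2 * math.pi)
            rad = max_off * math.sqrt(rng.uniform())
            y = cy + rad * math.sin(ang)
            x = cx + rad * math.cos(ang)
            ok = True
            for other in records:
                d = math.hypot(y - other.center[0], x - other.center[1])
                if d < r + other.radius + spec.min_separation:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise SpecError(
                f"could not place droplet {i}: tissue disc too crowded"
            )
        records.append(
            DropletRecord(
                droplet_id=i,
                z_center=z0,
                center=(float(y), float(x)),
                radius=float(r),
                peak_intensity=float(amplitude),
                slices=list(range(z0 - z_lo_off, z0 + z_hi_off + 1)),
            )
        )
    return records


def generate_stack(spec: SyntheticSpec) -> Tuple[ImageStack, GroundTruth]:
    """Render a synthetic stack and its ground truth.

    Tissue is a flat disc at ``tissue_intensity`` over ``background``; each
    droplet adds a solid cross-section disc of its amplitude on every slice
    it spans, with the cross-section radius shrinking away from the central
    slice as for a sphere.  The whole slice is then blurred with a Gaussian
    PSF, noise is added, and the result is quantized to the bit depth.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    records = _sample_droplets(spec, rng)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    cy, cx = spec.tissue_center
    tissue = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.tissue_radius**2
    base = np.full((ny, nx), spec.background, dtype=np.float64)
    base[tissue] = spec.tissue_intensity

    stack = np.empty((nz, ny, nx), dtype=np.float64)
    for z in range(nz):
        plane = base.copy()
        for rec in records:
            if z not in rec.slices:
                continue
            dz = z - rec.z_center
            e = len(rec.slices)
            half = (e + 1) / 2.0
            frac = 1.0 - (dz / half) ** 2
            rz = rec.radius * math.sqrt(max(frac, 0.0))
            if rz <= 0:
                continue
            y0, x0 = rec.center
            ylo, yhi = int(y0 - rz - 1), int(y0 + rz + 2)
            xlo, xhi = int(x0 - rz - 1), int(x0 + rz + 2)
            sub = (yy[ylo:yhi, xlo:xhi] - y0) ** 2 + (xx[ylo:yhi, xlo:xhi] - x0) ** 2
            plane[ylo:yhi, xlo:xhi][sub <= rz**2] += rec.peak_intensity
        if spec.psf_sigma > 0:
            plane = ndimage.gaussian_filter(plane, spec.psf_sigma, mode="reflect")
        if spec.poisson:
            plane = rng.poisson(np.clip(plane, 0, None)).astype(np.float64)
        if spec.effective_noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.effective_noise_sd, plane.shape)
        stack[z] = plane

    top = 2**spec.bit_depth - 1
    quantized = np.clip(np.rint(stack), 0, top).astype(
        np.uint8 if spec.bit_depth == 8 else np.uint16
    )
    image = ImageStack(voxels=quantized, bit_depth=spec.bit_depth,
                       source_path=f"synthetic(seed={spec.seed})")
    return image, GroundTruth(records=records)


def truth_to_frame(truth: GroundTruth):
    """Ground truth as a DataFrame (for CSV round trips)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "droplet_id": r.droplet_id,
                "z_center": r.z_center,
                "center_y": r.center[0],
                "center_x": r.center[1],
                "radius": r.radius,
                "peak_intensity": r.peak_intensity,
                "slices": ";".join(str(s) for s in r.slices),
            }
            for r in truth.records
        ],
        columns=[
            "droplet_id", "z_center", "center_y", "center_x",
            "radius", "peak_intensity", "slices",
        ],
    )


def truth_from_frame(df) -> GroundTruth:
    records = [
        DropletRecord(
            droplet_id=int(row.droplet_id),
            z_center=int(row.z_center),
            center=(float(row.center_y), float(row.center_x)),
            radius=float(row.radius),
            peak_intensity=float(row.peak_intensity),
            slices=[int(s) for s in str(row.slices).split(";") if s != ""],
        )
        for row in df.itertuples()
    ]
    return GroundTruth(records=records)


def match_and_score(detected, truth: GroundTruth, tol: float = 4.0) -> EvalMetrics:
    """Score retained detections against planted droplets.

    Greedy nearest-centroid matching in the (y, x) plane: candidate pairs
    are taken in order of increasing distance, each detection and each truth
    record used at most once, and a pair counts as a match iff its distance
    is at most ``tol`` pixels.  An empty detection set has precision 1 by
    convention (it asserts nothing false).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    kept = detected.kept() if hasattr(detected, "kept") else list(detected)
    n_det, n_truth = len(kept), len(truth)

    det_pts = np.array([p.centroid for p in kept], dtype=float).reshape(n_det, 2)
    tru_pts = np.array([r.center for r in truth.records], dtype=float).reshape(
        n_truth, 2
    )

    pairs = []
    for i in range(n_det):
        d = np.hypot(
            det_pts[i, 0] - tru_pts[:, 0], det_pts[i, 1] - tru_pts[:, 1]
        )
        for j in np.nonzero(d <= tol)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()

    det_used = [False] * n_det
    tru_used = [False] * n_truth
    matches = []
    for _, i, j in pairs:
        if det_used[i] or tru_used[j]:
            continue
        det_used[i] = True
        tru_used[j] = True
        matches.append((i, j))

    n_matched = len(matches)
    precision = 1.0 if n_det == 0 else n_matched / n_det
    recall = 1.0 if n_truth == 0 else n_matched / n_truth
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )

    if matches:
        errs = [
            abs(kept[i].pixel_count - math.pi * truth.records[j].radius ** 2)
            for i, j in matches
        ]
        size_err = float(np.mean(errs))
    else:
        size_err = None

    decile_recall: List[float] = []
    if n_truth:
        order = np.argsort([r.peak_intensity for r in truth.records], kind="stable")
        for chunk in np.array_split(order, 10):
            if len(chunk) == 0:
                decile_recall.append(float("nan"))
            else:
                decile_recall.append(
                    float(np.mean([tru_used[j] for j in chunk]))
                )

    return EvalMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        mean_abs_size_error_px2=size_err,
        decile_recall=decile_recall,
        n_detected=n_det,
        n_truth=n_truth,
        n_matched=n_matched,
    )
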