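"""Reading and writing image stacks, ROI masks, and particle tables.

Conventions
-----------
Coordinates are 0-based in (z, y, x) order with the origin at the top-left
corner of slice 0; bounding boxes are half-open.  Intensities are kept in
their native integer range — nothing in this module rescales voxel values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelError, DimensionError, FormatError

__all__ = [
    "ImageStack",
    "ROIMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_particles",
    "read_particles",
    "write_provenance",
    "PARTICLE_COLUMNS",
]

#: Column order of the particle CSV produced by :func:`write_particles`.
PARTICLE_COLUMNS = [
    "brain_id",
    "slice",
    "iteration",
    "centroid_x",
    "centroid_y",
    "area_px",
    "area_um2",
    "perimeter_px",
    "circularity",
    "mean_intensity",
    "max_intensity",
    "kept_after_dedup",
]


@dataclass
class ImageStack:
    """An ordered sequence of 2-D grayscale slices.

    Parameters
    ----------
    voxels
        Integer intensities, shape ``(z, y, x)``.
    bit_depth
        8 or 16; voxel values must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size_xy
        In-plane pixel size in micrometres, if known.
    z_step
        Distance between consecutive slices in micrometres, if known.
    """

    voxels: np.ndarray
    bit_depth: int
    pixel_size_xy: Optional[float] = None
    z_step: Optional[float] = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None, ...]
        if self.voxels.ndim != 3:
            raise DimensionError(
                f"stack must be 2-D or 3-D, got shape {self.voxels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        if self.voxels.size == 0:
            raise DimensionError("stack must contain at least one pixel")
        lo, hi = int(self.voxels.min()), int(self.voxels.max())
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def checksum(self) -> str:
        """SHA-256 of the raw voxel buffer (shape- and dtype-stable)."""
        h = hashlib.sha256()
        h.update(str(self.voxels.shape).encode())
        h.update(str(self.voxels.dtype).encode())
        h.update(np.ascontiguousarray(self.voxels).tobytes())
        return h.hexdigest()


@dataclass
class ROIMask:
    """Boolean mask congruent with a stack; restricts where particles count.

    A 2-D mask is broadcast over all slices on construction.
    ``origin`` records how the mask was obtained: ``"auto"`` (delineated),
    ``"file"`` (user-supplied), or ``"full-frame"`` (fallback).
    """

    mask: np.ndarray
    origin: str = "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise DimensionError(f"mask must be 2-D or 3-D, got {self.mask.ndim}-D")

    def broadcast(self, n_slices: int) -> "ROIMask":
        """Return a 3-D mask with ``n_slices`` identical planes if 2-D."""
        if self.mask.ndim == 3:
            return self
        m = np.broadcast_to(self.mask, (n_slices,) + self.mask.shape)
        return ROIMask(mask=np.ascontiguousarray(m), origin=self.origin)

    def plane(self, z: int) -> np.ndarray:
        """The 2-D mask for slice ``z`` (identical planes if built from 2-D)."""
        return self.mask[z] if self.mask.ndim == 3 else self.mask

    def validate_against(self, stack: ImageStack) -> None:
        yx = stack.voxels.shape[1:]
        if self.mask.ndim == 2:
            if self.mask.shape != yx:
                raise DimensionError(
                    f"mask shape {self.mask.shape} != slice shape {yx}"
                )
        elif self.mask.shape != stack.voxels.shape:
            raise DimensionError(
                f"mask shape {self.mask.shape} != stack shape {stack.voxels.shape}"
            )


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(
        f"unsupported dtype {arr.dtype}; only 8- and 16-bit grayscale TIFFs "
        "are accepted"
    )


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> Optional[float]:
    """Pixel size in µm from TIFF resolution tags, if resolvable."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    per_unit = num / den  # pixels per unit
    unit_val = getattr(unit, "value", None)
    # TIFF ResolutionUnit: 2 = inch, 3 = centimetre; anything else unitless.
    if unit_val == 2:
        return 25400.0 / per_unit
    if unit_val == 3:
        return 10000.0 / per_unit
    return None


def read_stack(path, channel: Optional[int] = None) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Bit depth is preserved — no rescaling.  Multichannel files are rejected
    unless ``channel`` selects a single channel, because a silent channel
    choice is a reproducibility hazard.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            pixel_size = _pixel_size_from_tags(tif)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc

    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4)):
        # (z, y, x, c) or (y, x, c)
        if arr.ndim == 3:
            arr = arr[None, ...]
        if channel is None:
            raise ChannelError(
                f"{path} has {arr.shape[-1]} channels; supply a single-channel "
                "image or pass a channel index (CLI: --channel)"
            )
        if not 0 <= channel < arr.shape[-1]:
            raise ChannelError(
                f"channel {channel} out of range for {arr.shape[-1]}-channel image"
            )
        arr = arr[..., channel]
    if arr.ndim != 3:
        raise FormatError(f"unsupported TIFF layout with shape {arr.shape}")

    return ImageStack(
        voxels=arr,
        bit_depth=_bit_depth_of(arr),
        pixel_size_xy=pixel_size,
        source_path=str(path),
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF; round-trips voxels bitwise."""
    tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")


def read_mask(path, stack: ImageStack) -> ROIMask:
    """Read a binary mask image (nonzero = inside) matching ``stack``."""
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read mask {path}: {exc}") from exc
    mask = ROIMask(mask=arr != 0, origin="file")
    mask.validate_against(stack)
    return mask.broadcast(stack.n_slices)


def write_mask(mask: ROIMask, path) -> None:
    arr = mask.mask
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(str(path), (arr.astype(np.uint8) * 255), photometric="minisblack")


def particles_to_frame(particle_set, pixel_size_xy: Optional[float] = None) -> pd.DataFrame:
    """Flatten a ParticleSet into the canonical CSV table.

    Rows are ordered by (slice, centroid_y, centroid_x) so that two runs on
    identical input produce byte-identical files.
    """
    rows = []
    for p in particle_set.particles:
        area_um2 = (
            p.pixel_count * pixel_size_xy**2 if pixel_size_xy is not None else None
        )
        rows.append(
            {
                "brain_id": particle_set.brain_id,
                "slice": p.slice_index,
                "iteration": p.iteration,
                "centroid_x": p.centroid[1],
                "centroid_y": p.centroid[0],
                "area_px": p.pixel_count,
                "area_um2": area_um2,
                "perimeter_px": p.perimeter,
                "circularity": p.circularity,
                "mean_intensity": p.mean_intensity,
                "max_intensity": p.max_intensity,
                "kept_after_dedup": p.kept_after_dedup,
            }
        )
    df = pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["slice", "centroid_y", "centroid_x"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_particles(particle_set, path, pixel_size_xy: Optional[float] = None) -> None:
    """Write the particle table CSV (header always present)."""
    df = particles_to_frame(particle_set, pixel_size_xy)
    df.to_csv(path, index=False)


def read_particles(path) -> pd.DataFrame:
    """Re-read a particle CSV written by :func:`write_particles`."""
    df = pd.read_csv(path)
    missing = set(PARTICLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"particle table {path} lacks columns {sorted(missing)}")
    return df


def write_provenance(path, *, config: dict, seed: Optional[int] = None,
                     inputs: Optional[dict] = None, version: str = "") -> None:
    """JSON sidecar recording everything needed to reproduce an output."""
    payload = {
        "tool": "dropletquant",
        "version": version,
        "config": config,
        "seed": seed,
        "inputs": inputs or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
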