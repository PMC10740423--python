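"""Volume preparation: HU rescaling, intensity normalization, cropping to
the labeled extent, fixed-size resampling (T1-style) and overlapping patch
tiling with lossless mean stitching (T2/T3-style).

CT scanners store raw integers; the DICOM rescale slope/intercept map them
to Hounsfield Units (HU). For training and inference, HU are clipped to
[-1024, 2500] (air to dense cortical bone), shifted to [0, 3524] and scaled
to [0, 1] so volumes from different scanners share one intensity scale.
Whole knees do not fit GPU-sized inputs at native resolution, hence either
a lossy fixed resample (192³) or overlapping fixed-size patches (160³, or
smaller at test scale) with mean-blend stitching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    CTVolume,
    ConfigurationError,
    DataQualityError,
    LabelVolume,
    logger,
)

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

#: Default clip window: air (-1024 HU) to high-density cortical bone (2500 HU).
DEFAULT_CLIP_LO = -1024.0
DEFAULT_CLIP_HI = 2500.0


@dataclass
class NormalizationParams:
    """Affine HU rescale + clip-shift-scale normalization parameters."""

    slope: float = 1.0
    intercept: float = 0.0
    clip_lo: float = DEFAULT_CLIP_LO
    clip_hi: float = DEFAULT_CLIP_HI

    def __post_init__(self) -> None:
        if not self.clip_lo < self.clip_hi:
            raise ConfigurationError(
                f"clip_lo ({self.clip_lo}) must be below clip_hi ({self.clip_hi})"
            )

    @property
    def range_width(self) -> float:
        return self.clip_hi - self.clip_lo


@dataclass
class CropRecord:
    """Inclusive per-axis index bounds of a crop, enough to invert it."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]  # inclusive
    original_shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        for a in range(3):
            if not (0 <= self.lo[a] <= self.hi[a] < self.original_shape[a]):
                raise DataQualityError(f"invalid crop bounds on axis {a}: {self}")

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))


@dataclass
class PatchGrid:
    """Placement of overlapping cubic patches tiling a volume."""

    patch_size: Tuple[int, int, int]
    starts: Tuple[List[int], List[int], List[int]]  # per-axis start indices
    volume_shape: Tuple[int, int, int]

    @property
    def overlaps(self) -> Tuple[int, int, int]:
        """Per-axis overlap between adjacent patches (0 when a single patch)."""
        out = []
        for a in range(3):
            s = self.starts[a]
            if len(s) < 2:
                out.append(0)
            else:
                out.append(max(self.patch_size[a] - (s[i + 1] - s[i])
                               for i in range(len(s) - 1)))
        return tuple(out)

    def placements(self) -> List[Tuple[int, int, int]]:
        """All patch corner indices, z-major order."""
        return [(i, j, k)
                for i in self.starts[0]
                for j in self.starts[1]
                for k in self.starts[2]]

    @property
    def n_patches(self) -> int:
        return len(self.starts[0]) * len(self.starts[1]) * len(self.starts[2])


# ---------------------------------------------------------------------------
# Intensity operations
# ---------------------------------------------------------------------------

def rescale_to_hu(raw: CTVolume, slope: float, intercept: float) -> CTVolume:
    """Map raw stored values to Hounsfield Units: ``HU = slope*raw + intercept``.

    ``slope`` and ``intercept`` come from the DICOM header (RescaleSlope
    (0028,1053) / RescaleIntercept (0028,1052)).
    """
    if slope is None or intercept is None:
        raise ConfigurationError(
            "missing rescale slope/intercept: DICOM tags (0028,1053) RescaleSlope "
            "and (0028,1052) RescaleIntercept are required"
        )
    if slope == 0:
        raise ConfigurationError("rescale slope must be nonzero")
    out = slope * np.asarray(raw.voxels, dtype=np.float64) + intercept
    return raw.with_voxels(out)


def normalize_intensity(hu: CTVolume, params: NormalizationParams | None = None) -> CTVolume:
    """Clip HU to [clip_lo, clip_hi], shift to positive and scale to [0, 1].

    With the defaults the window is [-1024, 2500] HU, the shifted range is
    [0, 3524], and the output is ``(clip(hu) - clip_lo) / 3524``.
    """
    params = params or NormalizationParams()
    v = np.asarray(hu.voxels, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise DataQualityError("non-finite voxel values in HU volume")
    out = (np.clip(v, params.clip_lo, params.clip_hi) - params.clip_lo) / params.range_width
    return hu.with_voxels(out)


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_to_label_extent(
    ct: CTVolume, labels: LabelVolume, margin: int = 0
) -> Tuple[CTVolume, LabelVolume, CropRecord]:
    """Crop both volumes to the tight bounding box of nonzero labels.

    The box is expanded by ``margin`` voxels per side and clamped to the
    volume. Mirrors discarding every axial/coronal/sagittal slice with no
    reference segmentation.
    """
    if ct.shape != labels.shape:
        raise DataQualityError("CT and label volumes must share a grid")
    fg = labels.voxels != 0
    if not fg.any():
        raise DataQualityError("no foreground to crop to: label volume is all zero")
    lo, hi = [], []
    for a in range(3):
        axes = tuple(i for i in range(3) if i != a)
        prof = fg.any(axis=axes)
        idx = np.flatnonzero(prof)
        lo.append(max(int(idx[0]) - margin, 0))
        hi.append(min(int(idx[-1]) + margin, labels.shape[a] - 1))
    rec = CropRecord(lo=tuple(lo), hi=tuple(hi), original_shape=labels.shape)
    sl = rec.slices()
    new_origin = tuple(o + l * s for o, l, s in zip(ct.origin, lo, ct.spacing))
    ct_out = CTVolume(ct.voxels[sl].copy(), spacing=ct.spacing, origin=new_origin)
    lb_out = LabelVolume(labels.voxels[sl].copy(), spacing=labels.spacing, origin=new_origin)
    logger.info("crop_to_label_extent: %s -> %s (margin %d)", labels.shape, ct_out.shape, margin)
    return ct_out, lb_out, rec


def uncrop(voxels: np.ndarray, rec: CropRecord, fill: float = 0) -> np.ndarray:
    """Place a cropped array back into its original extent (inverse of crop)."""
    out = np.full(rec.original_shape, fill, dtype=voxels.dtype)
    out[rec.slices()] = voxels
    return out


# ---------------------------------------------------------------------------
# Fixed-size resampling (T1 mode)
# ---------------------------------------------------------------------------

def resample_fixed(
    vol: CTVolume, target_shape: Sequence[int] = (192, 192, 192), is_label: bool = False
) -> CTVolume:
    """Resample to a fixed shape: trilinear for images, nearest for labels.

    Output voxel centers are placed with the "align extents" rule
    ``i_in = (i_out + 0.5) * L_in / L_out - 0.5`` so an identity resample is
    bit-exact; spacing is rescaled by the shape ratio.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ConfigurationError(f"target shape must be positive, got {target_shape}")
    if any(s <= 1 for s in vol.shape):
        raise DataQualityError(f"cannot resample degenerate volume of shape {vol.shape}")
    src = vol.voxels
    axes_coords = [
        (np.arange(t) + 0.5) * (l / t) - 0.5 for t, l in zip(target_shape, src.shape)
    ]
    grid = np.meshgrid(*axes_coords, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        src.astype(np.float64 if not is_label else src.dtype),
        coords, order=order, mode="nearest",
    ).reshape(target_shape)
    if is_label:
        out = out.astype(vol.voxels.dtype)
    new_spacing = tuple(s * l / t for s, l, t in zip(vol.spacing, src.shape, target_shape))
    new_origin = tuple(
        o + s * ((l / t) * 0.5 - 0.5) for o, s, l, t in zip(vol.origin, vol.spacing, src.shape, target_shape)
    )
    cls = LabelVolume if is_label else CTVolume
    return cls(out, spacing=new_spacing, origin=new_origin)


# ---------------------------------------------------------------------------
# Patch tiling (T2/T3 mode)
# ---------------------------------------------------------------------------

def plan_patches(volume_shape: Sequence[int], patch_size: int | Sequence[int] = 160) -> PatchGrid:
    """Plan per-axis patch starts: ``n = ceil(L/P)`` patches, starts evenly
    spread as ``round(i*(L-P)/(n-1))``, guaranteeing full coverage with the
    minimal patch count and maximal even overlap."""
    volume_shape = tuple(int(v) for v in volume_shape)
    if np.isscalar(patch_size):
        patch_size = (int(patch_size),) * 3
    patch_size = tuple(int(p) for p in patch_size)
    starts: List[List[int]] = []
    for a, (L, P) in enumerate(zip(volume_shape, patch_size)):
        if L < P:
            raise ConfigurationError(
                f"axis {a} length {L} is smaller than patch size {P}; "
                "pad the volume to the patch size first (pad_to_patch)"
            )
        n = math.ceil(L / P)
        if n == 1:
            s = [0]
        else:
            s = [int(round(i * (L - P) / (n - 1))) for i in range(n)]
        starts.append(s)
    return PatchGrid(patch_size=patch_size, starts=tuple(starts), volume_shape=volume_shape)


def pad_to_patch(voxels: np.ndarray, patch_size: int | Sequence[int]) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Symmetric zero-pad so every axis reaches the patch size.

    Returns the padded array and the per-axis (before, after) padding so it
    can be stripped after stitching.
    """
    if np.isscalar(patch_size):
        patch_size = (int(patch_size),) * 3
    pads = []
    for L, P in zip(voxels.shape, patch_size):
        deficit = max(P - L, 0)
        pads.append((deficit // 2, deficit - deficit // 2))
    return np.pad(voxels, pads, mode="constant"), pads


def strip_padding(voxels: np.ndarray, pads: List[Tuple[int, int]]) -> np.ndarray:
    sl = tuple(slice(b, voxels.shape[i] - a if a else None) for i, (b, a) in enumerate(pads))
    return voxels[sl]


def extract_patches(voxels: np.ndarray, grid: PatchGrid) -> List[np.ndarray]:
    """Cut the planned patches out of a volume (copies), z-major order."""
    P = grid.patch_size
    return [voxels[i:i + P[0], j:j + P[1], k:k + P[2]].copy()
            for (i, j, k) in grid.placements()]


def stitch_patches(patch_outputs: Sequence[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Blend per-patch score blocks back into a volume by the mean rule.

    Each voxel's value is the arithmetic mean of all patch blocks covering
    it; a voxel covered once is copied exactly. Blocks may carry a leading
    channel axis (C, pz, py, px) or be plain (pz, py, px).
    """
    placements = grid.placements()
    if len(patch_outputs) != len(placements):
        raise DataQualityError(
            f"got {len(patch_outputs)} blocks for {len(placements)} planned patches"
        )
    P = grid.patch_size
    first = np.asarray(patch_outputs[0])
    has_channels = first.ndim == 4
    spatial = first.shape[1:] if has_channels else first.shape
    if tuple(spatial) != tuple(P):
        raise DataQualityError(f"block spatial shape {spatial} != patch size {P}")
    out_shape = (first.shape[0],) + grid.volume_shape if has_channels else grid.volume_shape
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(grid.volume_shape, dtype=np.float64)
    for blk, (i, j, k) in zip(patch_outputs, placements):
        blk = np.asarray(blk)
        sl = (slice(i, i + P[0]), slice(j, j + P[1]), slice(k, k + P[2]))
        if has_channels:
            acc[(slice(None),) + sl] += blk
        else:
            acc[sl] += blk
        cnt[sl] += 1.0
    return acc / cnt
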