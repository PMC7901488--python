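"""Preprocessing: lung-mask cropping, grayscale truncation, resizing,
max-min normalization.

The network consumes fixed-size inputs (default 256x256 in-plane, 32
slices) with intensities in [0, 1].  A case is prepared by cropping the CT
to the lung bounding box, clamping HU into a truncation window (default
[-1000, 400], covering air through soft tissue and excluding metal),
resizing — trilinear for images, nearest-neighbour for masks so they stay
binary — and finally max-min normalizing, so the truncation window defines
the effective intensity range.  Depth reaches the target slice count by
interpolation rather than padding or cropping.

Crop geometry is recorded so predictions can be mapped back to the
original voxel grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .ct_io import BinaryMask3D, CTVolume, _require_grid
from .lungseg import crop_to_box, lung_bounding_box
from .resample import resize_linear, resize_nearest


@dataclass(frozen=True)
class PreprocessParams:
    """Target geometry and HU truncation window for network inputs."""

    target_inplane: int = 256
    target_depth: int = 32
    clip_low: float = -1000.0
    clip_high: float = 400.0
    crop_margin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.clip_low >= self.clip_high:
            raise ValueError(
                f"clip_low must be below clip_high, got [{self.clip_low}, {self.clip_high}]"
            )
        if self.target_inplane < 8 or self.target_depth < 8:
            raise ValueError("target_inplane and target_depth must be >= 8")

    @property
    def target_shape(self) -> tuple[int, int, int]:
        return (self.target_inplane, self.target_inplane, self.target_depth)


def truncate_gray(volume: CTVolume, clip_low: float, clip_high: float) -> CTVolume:
    """Clamp every voxel into [clip_low, clip_high]."""
    if clip_low >= clip_high:
        raise ValueError(f"inverted truncation bounds [{clip_low}, {clip_high}]")
    out = np.clip(volume.voxels, clip_low, clip_high)
    return CTVolume(voxels=out, spacing=volume.spacing, affine=volume.affine)


def minmax_normalize(volume: CTVolume) -> CTVolume:
    """Rescale intensities linearly to [0, 1] via (x - min) / (max - min)."""
    v = volume.voxels.astype(np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("constant-valued volume has zero dynamic range; cannot normalize")
    out = ((v - lo) / (hi - lo)).astype(np.float32)
    return CTVolume(voxels=out, spacing=volume.spacing, affine=volume.affine)


def _resized_geometry(vol, shape: tuple[int, int, int]):
    scale = np.array(vol.voxels.shape, dtype=float) / np.array(shape, dtype=float)
    spacing = tuple(float(s * f) for s, f in zip(vol.spacing, scale))
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] * scale[np.newaxis, :]
    # keep pixel-centre correspondence of the resampling convention
    affine[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ ((scale - 1.0) / 2.0)
    return spacing, affine


def resize_volume(vol: CTVolume | BinaryMask3D, params: PreprocessParams,
                  is_mask: bool | None = None):
    """Resize to the target grid: trilinear for images, nearest for masks.

    Spacing and affine are rescaled so the physical extent is preserved.
    """
    shape = params.target_shape
    if is_mask is None:
        is_mask = isinstance(vol, BinaryMask3D)
    spacing, affine = _resized_geometry(vol, shape)
    if is_mask:
        out = resize_nearest(vol.voxels, shape)
        return BinaryMask3D(voxels=out, spacing=spacing, affine=affine)
    out = resize_linear(vol.voxels.astype(np.float32), shape)
    return CTVolume(voxels=out, spacing=spacing, affine=affine)


@dataclass
class PreprocessedCase:
    """Network-ready image/mask pair plus the geometry to undo the crop."""

    image: CTVolume
    mask: BinaryMask3D | None
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    original_shape: tuple[int, int, int]
    params: PreprocessParams

    def sidecar(self) -> dict:
        return {
            "crop_box": [list(b) for b in self.crop_box],
            "original_shape": list(self.original_shape),
            "target_shape": list(self.params.target_shape),
            "clip": [self.params.clip_low, self.params.clip_high],
        }

    def write_sidecar(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(json.dumps(self.sidecar(), indent=1))
        return p


def preprocess_case(
    volume: CTVolume,
    lung_mask: BinaryMask3D,
    mask: BinaryMask3D | None = None,
    params: PreprocessParams | None = None,
) -> PreprocessedCase:
    """Crop to lungs, truncate, resize and normalize one case.

    The lesion mask (when given) follows the identical crop and a
    nearest-neighbour resize, so image and mask stay voxel-aligned.
    """
    params = params or PreprocessParams()
    _require_grid(volume, lung_mask, "volume and lung mask")
    if mask is not None:
        _require_grid(volume, mask, "volume and lesion mask")

    box = lung_bounding_box(lung_mask, params.crop_margin)
    img = crop_to_box(volume, box)
    img = truncate_gray(img, params.clip_low, params.clip_high)
    img = resize_volume(img, params, is_mask=False)
    img = minmax_normalize(img)

    out_mask = None
    if mask is not None:
        m = crop_to_box(mask, box)
        out_mask = resize_volume(m, params, is_mask=True)

    crop = tuple((int(b.start), int(b.stop)) for b in box)
    return PreprocessedCase(
        image=img,
        mask=out_mask,
        crop_box=crop,  # type: ignore[arg-type]
        original_shape=tuple(volume.voxels.shape),  # type: ignore[arg-type]
        params=params,
    )
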