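"""Rule-based lung-mask extraction from chest CT.

The pipeline is classical threshold-plus-morphology: binarize at -300 HU
(tissue above, air below), invert to get air-like voxels, discard air
connected to the volume boundary (outside air, and the air around the
scanner bed), keep the largest interior air components — the lungs — and
drop small noise components.  The lesion region is then localized by
cropping the CT to the lung bounding box, since the anterior mediastinum
lies between the two lungs.

Voxels exactly at the threshold count as air (background side): the
threshold rule is strictly "greater than", which keeps the tissue mask
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import BinaryMask3D, CTVolume, _require_grid

DEFAULT_HU_THRESHOLD = -300.0


@dataclass(frozen=True)
class LungSegParams:
    """Parameters of the threshold-and-morphology lung segmenter.

    connectivity follows the scipy convention: 1 = faces only
    (6-neighbourhood), 3 = faces+edges+corners (26-neighbourhood).  Face
    connectivity is the default because it prevents diagonal leakage
    between the lungs and outside air through thin chest walls.
    """

    hu_threshold: float = DEFAULT_HU_THRESHOLD
    connectivity: int = 1
    min_component_voxels: int = 64
    keep_top_k: int = 2

    def __post_init__(self) -> None:
        if self.keep_top_k not in (1, 2):
            raise ValueError(f"keep_top_k must be 1 or 2, got {self.keep_top_k}")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")
        if self.connectivity not in (1, 2, 3):
            raise ValueError(f"connectivity must be 1, 2 or 3, got {self.connectivity}")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, connectivity)


def threshold_ct(volume: CTVolume, hu_threshold: float = DEFAULT_HU_THRESHOLD) -> BinaryMask3D:
    """Binarize a CT at an HU cutoff: 1 where HU > threshold, else 0."""
    mask = (volume.voxels > hu_threshold).astype(np.uint8)
    return BinaryMask3D(voxels=mask, spacing=volume.spacing, affine=volume.affine)


def invert_mask(mask: BinaryMask3D) -> BinaryMask3D:
    """Swap foreground and background voxel-wise."""
    return BinaryMask3D(voxels=(1 - mask.voxels).astype(np.uint8),
                        spacing=mask.spacing, affine=mask.affine)


def largest_connected_component(mask: BinaryMask3D, connectivity: int = 1) -> BinaryMask3D:
    """Keep only the largest connected foreground component.

    Ties are broken by the component whose first voxel comes earliest in
    scan order (this is the lowest scipy label).  Raises if the mask has
    no foreground.
    """
    labels, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    if n == 0:
        raise ValueError("mask has no foreground voxels; no connected component exists")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))  # argmax returns the lowest index on ties
    return BinaryMask3D(voxels=(labels == best).astype(np.uint8),
                        spacing=mask.spacing, affine=mask.affine)


def remove_border_connected(mask: BinaryMask3D, connectivity: int = 1) -> BinaryMask3D:
    """Remove foreground components touching any face of the volume."""
    labels, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    if n == 0:
        return BinaryMask3D(voxels=np.zeros_like(mask.voxels),
                            spacing=mask.spacing, affine=mask.affine)
    border = np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ])
    drop = np.unique(border)
    keep = np.ones(n + 1, dtype=bool)
    keep[drop] = False
    keep[0] = False
    return BinaryMask3D(voxels=keep[labels].astype(np.uint8),
                        spacing=mask.spacing, affine=mask.affine)


def extract_lung_mask(volume: CTVolume, params: LungSegParams | None = None) -> BinaryMask3D:
    """Extract the lung mask: threshold, invert, drop border air, keep lungs.

    Steps: binarize at ``hu_threshold`` (tissue=1); invert to air; remove
    air components touching the volume boundary (outside air and the air
    around the bed plate); among interior air components, drop those below
    ``min_component_voxels`` and keep the ``keep_top_k`` largest.  Raises
    if no interior air component remains.
    """
    params = params or LungSegParams()
    tissue = threshold_ct(volume, params.hu_threshold)
    air = invert_mask(tissue)
    interior = remove_border_connected(air, params.connectivity)

    labels, n = ndimage.label(interior.voxels, structure=_structure(params.connectivity))
    if n == 0:
        raise ValueError(
            "no interior air component found — the volume may contain no lungs, "
            "or hu_threshold may be misconfigured for this image"
        )
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(-sizes, kind="stable")  # stable: ties keep lower label first
    chosen = [int(l) for l in order[: params.keep_top_k]
              if sizes[l] > 0 and sizes[l] >= params.min_component_voxels]
    if not chosen:
        raise ValueError(
            "all interior air components fall below min_component_voxels="
            f"{params.min_component_voxels}; threshold or phantom likely misconfigured"
        )
    lung = np.isin(labels, chosen).astype(np.uint8)
    return BinaryMask3D(voxels=lung, spacing=volume.spacing, affine=volume.affine)


def lung_bounding_box(
    lung_mask: BinaryMask3D,
    margin_voxels: tuple[int, int, int] = (0, 0, 0),
) -> tuple[slice, slice, slice]:
    """Tight bounding box of the mask, expanded by per-axis margins and
    clamped to the volume; half-open 0-based slices."""
    if lung_mask.count() == 0:
        raise ValueError("empty lung mask: cannot compute a bounding box")
    out = []
    arr = lung_mask.voxels
    for ax, m in enumerate(margin_voxels):
        proj = np.any(arr, axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - int(m), 0)
        hi = min(int(idx[-1]) + 1 + int(m), arr.shape[ax])
        out.append(slice(lo, hi))
    return tuple(out)  # type: ignore[return-value]


def crop_to_box(vol: CTVolume | BinaryMask3D, box: tuple[slice, slice, slice]):
    """Crop a volume or mask to a box, updating the affine so the world
    coordinates of retained voxels are unchanged."""
    sub = vol.voxels[box[0], box[1], box[2]]
    affine = vol.affine.copy()
    offset = np.array([box[0].start, box[1].start, box[2].start], dtype=float)
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ offset
    cls = type(vol)
    return cls(voxels=sub.copy(), spacing=vol.spacing, affine=affine)


def crop_to_lungs(
    volume: CTVolume,
    lung_mask: BinaryMask3D,
    margin_voxels: tuple[int, int, int] = (0, 0, 0),
) -> CTVolume:
    """Crop the CT to the lung-mask bounding box plus margins."""
    _require_grid(volume, lung_mask, "volume and lung mask")
    box = lung_bounding_box(lung_mask, margin_voxels)
    return crop_to_box(volume, box)
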