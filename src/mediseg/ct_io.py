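"""Reading and writing CT volumes and binary masks.

NIfTI-1 is the canonical interchange format; DICOM series are read-only
ingestion.  On load every volume is reoriented to the closest canonical
(RAS) axis order so that downstream thresholding and bed-removal logic
always sees the same anatomical layout: array axes are (rows, columns,
slices) = (H, W, D), with the slice axis running inferior-superior.

Voxel values are Hounsfield units.  DICOM stored values are converted via
``HU = slope * stored + intercept``.  Images round-trip losslessly when
integer-valued (written as int16); float data is written as float32.
Masks are stored as unsigned 8-bit with values restricted to {0, 1}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom


@dataclass
class CTVolume:
    """A 3D scalar field in Hounsfield units with spacing and affine.

    Attributes
    ----------
    voxels : np.ndarray
        3D array, axes (H, W, D).
    spacing : tuple of float
        Physical voxel size per axis in millimetres; strictly positive.
    affine : np.ndarray
        4x4 voxel-to-world transform.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask3D:
    """A voxel-aligned {0,1} field sharing a CTVolume's grid conventions."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            bad = [v for v in vals.tolist() if v not in (0, 1)]
            raise ValueError(f"mask contains values outside {{0,1}}: {bad[:5]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


def grid_compatible(a: CTVolume | BinaryMask3D, b: CTVolume | BinaryMask3D) -> bool:
    """True when two fields share the same voxel grid (shape and affine)."""
    return a.voxels.shape == b.voxels.shape and np.allclose(a.affine, b.affine, atol=1e-6)


def _require_grid(a, b, what: str = "inputs") -> None:
    if not grid_compatible(a, b):
        raise ValueError(
            f"{what} are not grid-compatible: shapes {a.voxels.shape} vs "
            f"{b.voxels.shape} or affines differ"
        )


# ---------------------------------------------------------------------------
# NIfTI


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several subclasses
        raise ValueError(f"cannot read {path} as a medical image: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), np.asarray(img.affine, dtype=float)


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM stored values are rescaled to HU using the per-slice rescale
    slope and intercept.  Raises on missing paths, unreadable payloads and
    DICOM series with inconsistent slice spacing.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        return _read_dicom_series(p)
    data, spacing, affine = _load_nifti(p)
    return CTVolume(voxels=data, spacing=spacing, affine=affine)


def read_mask(path: str | os.PathLike) -> BinaryMask3D:
    """Read a binary mask from NIfTI, validating that values are in {0,1}."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    data, spacing, affine = _load_nifti(p)
    return BinaryMask3D(voxels=data, spacing=spacing, affine=affine)


def write_volume(volume: CTVolume | BinaryMask3D, path: str | os.PathLike) -> Path:
    """Write a volume or mask as NIfTI-1.

    Integer-valued HU data is stored as int16 (lossless); other data as
    float32.  Masks go out as uint8.  Returns the written path.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    arr = volume.voxels
    if isinstance(volume, BinaryMask3D):
        out = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.int16)
    elif np.all(arr == np.round(arr)) and np.abs(arr).max(initial=0) < 32767:
        out = arr.astype(np.int16)
    else:
        out = arr.astype(np.float32)
    img = nib.Nifti1Image(out, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(p))
    return p


# ---------------------------------------------------------------------------
# DICOM series ingestion


def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(f for f in directory.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if not hasattr(ds, "pixel_array"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"{directory}: no readable DICOM slices found")

    def z_of(ds) -> float:
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in slices], dtype=float)
    if len(slices) > 1:
        gaps = np.diff(zs)
        if gaps.max() - gaps.min() > 1e-3 * max(1.0, abs(gaps.mean())):
            i = int(np.argmax(np.abs(gaps - gaps.mean())))
            raise ValueError(
                "inconsistent DICOM slice spacing: gap of "
                f"{gaps[i]:.4f} mm between slices {i} and {i + 1} "
                f"(expected {gaps.mean():.4f} mm)"
            )
        dz = float(abs(gaps.mean())) if len(gaps) else 1.0
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    vol = np.stack(planes, axis=-1)  # (rows, cols, slices)
    if np.all(vol == np.round(vol)):
        vol = vol.astype(np.int16)
    else:
        vol = vol.astype(np.float32)

    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    spacing = (float(ps[0]), float(ps[1]), dz)
    origin = getattr(slices[0], "ImagePositionPatient", [0.0, 0.0, 0.0])
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = [float(origin[0]), float(origin[1]), float(origin[2])]
    return CTVolume(voxels=vol, spacing=spacing, affine=affine)
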