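"""Synthetic HU-calibrated thorax phantoms with exact ground truth.

The phantom is the minimal thorax a threshold-and-morphology lung
segmenter cares about: an elliptic-cylinder soft-tissue body surrounded by
air, two ellipsoidal lungs inside it, a flat scanner-bed plate below the
body (separated from it by an air gap), and an ellipsoidal lesion placed
in the gap between the lungs — the anterior-mediastinum analogue.  HU
means are chosen so that air and lung parenchyma fall below the -300 HU
tissue threshold while body, lesion and bed fall above it, and so that
lesion/body contrast is low (default 5 HU), mimicking the low-contrast
lesions the segmentation task is hard for.

Noise is additive Gaussian, clipped to the 12-bit CT range [-1024, 3071].
Everything is driven by a single integer seed: the same spec always yields
a bit-identical phantom.

Geometry is expressed in fractional coordinates of the (H, W, D) =
(rows, columns, slices) grid, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ct_io import BinaryMask3D, CTVolume, write_volume

# Fixed anatomy (fractions of each axis). The body is an elliptic cylinder
# spanning the full slice range; lungs are ellipsoids strictly inside it and
# strictly away from every volume face, so interior-air extraction can
# recover them exactly.
_BODY_CENTER = (0.52, 0.50)
_BODY_SEMI = (0.34, 0.42)
_LUNG_CENTERS = ((0.45, 0.28), (0.45, 0.72))
_LUNG_SEMI = (0.17, 0.12, 0.33)
_LUNG_DEPTH_CENTER = 0.5
_BED_ROWS = (0.92, 0.96)
_BED_COLS = (0.08, 0.92)

_AXIS_NAMES = ("H", "W", "D")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for a synthetic thorax volume.

    HU defaults: air -1000, lung -800, body +40, lesion +45, bed +200.
    The |lesion - body| contrast of 5 HU is deliberately small and
    configurable, so tests can tune task difficulty.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 48)
    hu_air: float = -1000.0
    hu_lung: float = -800.0
    hu_body: float = 40.0
    hu_lesion: float = 45.0
    hu_bed: float = 200.0
    lesion_center: tuple[float, float, float] = (0.46, 0.50, 0.50)
    lesion_radii: tuple[float, float, float] = (0.08, 0.05, 0.10)
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(int(s) < 16 for s in self.volume_shape):
            bad = [i for i, s in enumerate(self.volume_shape) if int(s) < 16]
            axes = ", ".join(_AXIS_NAMES[i] for i in bad) or "all"
            raise ValueError(
                f"degenerate volume_shape {tuple(self.volume_shape)}: axis {axes} < 16 voxels"
            )
        for name in ("hu_air", "hu_lung"):
            if getattr(self, name) >= -300:
                raise ValueError(f"{name} must be below -300 HU, got {getattr(self, name)}")
        for name in ("hu_body", "hu_lesion", "hu_bed"):
            if getattr(self, name) <= -300:
                raise ValueError(f"{name} must be above -300 HU, got {getattr(self, name)}")
        if any(r <= 0 for r in self.lesion_radii):
            raise ValueError(f"lesion radii must be positive, got {self.lesion_radii}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._check_lesion_placement()

    def _check_lesion_placement(self) -> None:
        c, r = self.lesion_center, self.lesion_radii
        # inside the body cylinder, by axis-aligned extents
        body_lo = (_BODY_CENTER[0] - _BODY_SEMI[0], _BODY_CENTER[1] - _BODY_SEMI[1], 0.0)
        body_hi = (_BODY_CENTER[0] + _BODY_SEMI[0], _BODY_CENTER[1] + _BODY_SEMI[1], 1.0)
        for i in range(3):
            if c[i] - r[i] < body_lo[i] or c[i] + r[i] > body_hi[i]:
                raise ValueError(
                    f"lesion extends outside the body along axis {_AXIS_NAMES[i]}: "
                    f"extent [{c[i] - r[i]:.3f}, {c[i] + r[i]:.3f}] vs "
                    f"body [{body_lo[i]:.3f}, {body_hi[i]:.3f}]"
                )
        # strictly between the lungs: lesion W extent inside the inter-lung gap
        gap_lo = _LUNG_CENTERS[0][1] + _LUNG_SEMI[1]
        gap_hi = _LUNG_CENTERS[1][1] - _LUNG_SEMI[1]
        if c[1] - r[1] < gap_lo or c[1] + r[1] > gap_hi:
            raise ValueError(
                "lesion is not strictly between the two lungs along axis W: "
                f"extent [{c[1] - r[1]:.3f}, {c[1] + r[1]:.3f}] vs "
                f"inter-lung gap [{gap_lo:.3f}, {gap_hi:.3f}]"
            )


@dataclass
class PhantomSample:
    """A generated phantom with its exact generative truth masks."""

    image: CTVolume
    lesion_mask: BinaryMask3D
    lung_mask_truth: BinaryMask3D
    body_mask_truth: BinaryMask3D
    bed_mask_truth: BinaryMask3D


def _frac_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # voxel-centre fractional coordinates
    axes = [(np.arange(n) + 0.5) / n for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)  # type: ignore[return-value]


def _ellipsoid(grids, center, semi) -> np.ndarray:
    r, c, z = grids
    return (
        ((r - center[0]) / semi[0]) ** 2
        + ((c - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a phantom volume and its truth masks from a spec.

    With ``noise_sd=0`` every voxel equals exactly one of the five organ HU
    means, and thresholding at -300 HU recovers body+lesion+bed exactly.
    """
    shape = tuple(int(s) for s in spec.volume_shape)
    grids = _frac_grids(shape)
    r, c, z = grids

    body = (((r - _BODY_CENTER[0]) / _BODY_SEMI[0]) ** 2
            + ((c - _BODY_CENTER[1]) / _BODY_SEMI[1]) ** 2) <= 1.0
    body = np.broadcast_to(body, shape).copy()

    lungs = np.zeros(shape, dtype=bool)
    for lc in _LUNG_CENTERS:
        lungs |= _ellipsoid(grids, (lc[0], lc[1], _LUNG_DEPTH_CENTER), _LUNG_SEMI)
    lungs &= body

    lesion = _ellipsoid(grids, spec.lesion_center, spec.lesion_radii)
    lesion &= body
    lesion &= ~lungs  # guaranteed empty intersection by spec validation

    bed = ((r >= _BED_ROWS[0]) & (r < _BED_ROWS[1])
           & (c >= _BED_COLS[0]) & (c < _BED_COLS[1]))
    bed = np.broadcast_to(bed, shape) & ~body

    soft = body & ~lungs & ~lesion

    image = np.full(shape, spec.hu_air, dtype=np.float32)
    image[soft] = spec.hu_body
    image[lungs] = spec.hu_lung
    image[lesion] = spec.hu_lesion
    image[bed] = spec.hu_bed

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        np.clip(image, -1024.0, 3071.0, out=image)

    affine = np.eye(4)
    vol = CTVolume(voxels=image, spacing=(1.0, 1.0, 1.0), affine=affine)
    mk = lambda m: BinaryMask3D(voxels=m.astype(np.uint8), spacing=vol.spacing, affine=affine)
    return PhantomSample(
        image=vol,
        lesion_mask=mk(lesion),
        lung_mask_truth=mk(lungs),
        body_mask_truth=mk(soft),
        bed_mask_truth=mk(bed),
    )


def generate_dataset(
    spec: PhantomSpec,
    n: int,
    seed: int,
    center_jitter_sd: float = 0.02,
    radii_jitter_sd: float = 0.01,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with jittered lesion geometry.

    Lesion centres and semi-axes receive additive Gaussian jitter
    (``center_jitter_sd`` / ``radii_jitter_sd``, fractional units); each
    sample's noise seed derives deterministically from ``seed``.  Jitters
    that would violate placement invariants are resampled (rejection), so
    every returned sample is a valid phantom.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for _ in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for _attempt in range(100):
            center = tuple(np.asarray(spec.lesion_center) + rng.normal(0, center_jitter_sd, 3))
            radii = tuple(np.abs(np.asarray(spec.lesion_radii) + rng.normal(0, radii_jitter_sd, 3)))
            try:
                s = replace(spec, lesion_center=center, lesion_radii=radii, seed=sub_seed)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not place a jittered lesion in 100 attempts; "
                               "jitter SDs too large for the anatomy")
        samples.append(generate_phantom(s))
    return samples


def save_sample(sample: PhantomSample, directory: str | Path, stem: str = "phantom") -> dict[str, Path]:
    """Write image and truth masks as NIfTI files; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": write_volume(sample.image, d / f"{stem}_image.nii.gz"),
        "lesion_mask": write_volume(sample.lesion_mask, d / f"{stem}_lesion.nii.gz"),
        "lung_mask": write_volume(sample.lung_mask_truth, d / f"{stem}_lung.nii.gz"),
        "body_mask": write_volume(sample.body_mask_truth, d / f"{stem}_body.nii.gz"),
    }
    return paths
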