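"""Two-stage coarse-to-fine cascade.

Stage 1 sees the input downsampled by ``coarse_factor`` and localizes the
lesion at a rough scale; its probability map is trilinearly upsampled back
to full resolution (and renormalized onto the probability simplex), then
concatenated channel-wise with the high-resolution image as the input of
stage 2, which refines the segmentation.  Both stages share all
hyperparameters except the input channel count.  The whole cascade is
differentiable end to end: gradients reach stage 1 both through its own
supervision term and through the bridged probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .backbone import Backbone, BackboneConfig
from .ct_io import BinaryMask3D, CTVolume
from .lungseg import LungSegParams, extract_lung_mask
from .nn.layers import Module, softmax_channels
from .preprocess import PreprocessParams, preprocess_case
from .resample import resize_linear, resize_linear_adjoint, resize_nearest

_BRIDGES = ("probabilities", "labels")


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of both stages plus the cascade wiring."""

    stage1: BackboneConfig
    stage2: BackboneConfig
    coarse_factor: int = 2
    bridge: str = "probabilities"

    def __post_init__(self) -> None:
        cf = self.coarse_factor
        if cf < 1 or (cf & (cf - 1)) != 0:
            raise ValueError(f"coarse_factor must be a power of 2 >= 1, got {cf}")
        if self.bridge not in _BRIDGES:
            raise ValueError(f"bridge must be one of {_BRIDGES}, got {self.bridge!r}")
        bridged = self.stage1.num_classes if self.bridge == "probabilities" else 1
        want = self.stage1.in_channels + bridged
        if self.stage2.in_channels != want:
            raise ValueError(
                f"stage2 in_channels must be image channels + bridged channels = {want}, "
                f"got {self.stage2.in_channels}"
            )
        # the two stages must agree on everything except in_channels
        a = {k: v for k, v in asdict(self.stage1).items() if k != "in_channels"}
        b = {k: v for k, v in asdict(self.stage2).items() if k != "in_channels"}
        if a != b:
            diff = sorted(k for k in a if a[k] != b[k])
            raise ValueError(f"stage configs differ beyond in_channels: {diff}")

    @classmethod
    def build(cls, stage: BackboneConfig | None = None, coarse_factor: int = 2,
              bridge: str = "probabilities") -> "CascadeConfig":
        """Derive a consistent two-stage config from a single stage config."""
        stage = stage or BackboneConfig()
        bridged = stage.num_classes if bridge == "probabilities" else 1
        stage2 = replace(stage, in_channels=stage.in_channels + bridged)
        return cls(stage1=stage, stage2=stage2, coarse_factor=coarse_factor, bridge=bridge)

    def validate_shape(self, spatial: tuple[int, int, int]) -> None:
        for ax, s in zip("HWD", spatial):
            if s % self.coarse_factor:
                raise ValueError(
                    f"spatial dim {s} on axis {ax} not divisible by coarse_factor={self.coarse_factor}"
                )
        self.stage2.validate_shape(spatial)
        self.stage1.validate_shape(tuple(s // self.coarse_factor for s in spatial))


class CascadeModel(Module):
    """The two backbones plus the coarse-to-fine plumbing."""

    def __init__(self, config: CascadeConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(seed)
        s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        self.stage1 = self.add("stage1", Backbone(config.stage1, seed=s1))
        self.stage2 = self.add("stage2", Backbone(config.stage2, seed=s2))
        self._cache = None

    # -- stage 1 -----------------------------------------------------------
    def stage1_forward(self, image: np.ndarray, train: bool = False):
        """Coarse pass: downsample, segment, upsample, renormalize.

        Returns the full-resolution probability map; with ``train=True``
        also the coarse logits and the caches the backward pass needs.
        """
        if image.ndim == 3:
            image = image[np.newaxis]
        self.config.validate_shape(image.shape[1:])
        cf = self.config.coarse_factor
        coarse_shape = tuple(s // cf for s in image.shape[1:])
        down = resize_linear(image.astype(self.dtype), coarse_shape)
        logits1 = self.stage1.forward(down)
        p1c = softmax_channels(logits1.astype(np.float64))
        up = resize_linear(p1c, image.shape[1:])
        clipped = np.clip(up, 1e-7, None)
        z = clipped.sum(axis=0, keepdims=True)
        p1 = clipped / z
        if train:
            return p1, logits1, (p1c, up, clipped, z, coarse_shape)
        return p1

    def _bridge_channels(self, p1: np.ndarray) -> np.ndarray:
        if self.config.bridge == "labels":
            return np.argmax(p1, axis=0, keepdims=True).astype(self.dtype)
        return p1.astype(self.dtype)

    # -- full cascade ------------------------------------------------------
    def forward_train(self, image: np.ndarray):
        """Forward pass keeping everything backward needs.

        Returns (coarse stage-1 probability map, full-res stage-2
        probability map); logits are cached internally.
        """
        if image.ndim == 3:
            image = image[np.newaxis]
        p1, logits1, s1cache = self.stage1_forward(image, train=True)
        x2 = np.concatenate([image.astype(self.dtype), self._bridge_channels(p1)], axis=0)
        logits2 = self.stage2.forward(x2)
        p2 = softmax_channels(logits2.astype(np.float64))
        self._cache = (image, s1cache, p1, p2,
                       softmax_channels(logits1.astype(np.float64)))
        return self._cache[4], p2

    def backward(self, dlogits1: np.ndarray, dlogits2: np.ndarray) -> None:
        """Backpropagate given gradients w.r.t. both stages' logits.

        ``dlogits1`` is on the coarse grid (stage-1 supervision);
        ``dlogits2`` on the full grid.  The bridge path's contribution to
        stage 1 is added automatically (unless bridging argmax labels,
        which is non-differentiable and treated as constant).
        """
        image, (p1c, up, clipped, z, coarse_shape), p1, _, _ = self._cache
        dx2 = self.stage2.backward(dlogits2.astype(self.dtype))
        n_img = image.shape[0]
        d_bridge = dx2[n_img:].astype(np.float64)

        dl1 = np.asarray(dlogits1, dtype=np.float64)
        if self.config.bridge == "probabilities":
            # renormalization p = c / z
            dclipped = d_bridge / z - (d_bridge * clipped).sum(axis=0, keepdims=True) / (z * z)
            dup = dclipped * (up >= 1e-7)
            dp1c = resize_linear_adjoint(dup, coarse_shape)
            # softmax Jacobian at the coarse grid
            dl1 = dl1 + p1c * (dp1c - (dp1c * p1c).sum(axis=0, keepdims=True))
        self.stage1.backward(dl1.astype(self.dtype))

    def cascade_forward(self, image: np.ndarray) -> np.ndarray:
        """Inference pass: full-resolution stage-2 probability map."""
        if image.ndim == 3:
            image = image[np.newaxis]
        p1 = self.stage1_forward(image)
        x2 = np.concatenate([image.astype(self.dtype), self._bridge_channels(p1)], axis=0)
        return softmax_channels(self.stage2.forward(x2).astype(np.float64))


def cascade_forward(image: np.ndarray, config: CascadeConfig, seed: int = 0,
                    model: CascadeModel | None = None) -> np.ndarray:
    """Convenience wrapper mirroring :func:`backbone_forward`."""
    net = model if model is not None else CascadeModel(config, seed=seed)
    return net.cascade_forward(image)


def predict_case(
    volume: CTVolume,
    model: CascadeModel,
    lungseg_params: LungSegParams | None = None,
    preprocess_params: PreprocessParams | None = None,
) -> BinaryMask3D:
    """End-to-end inference: lung crop, preprocess, cascade, paste back.

    The argmax-binarized prediction is resized (nearest neighbour) to the
    crop box and pasted into a zero volume of the original shape, so the
    returned mask lives on the input CT's voxel grid.
    """
    pre = preprocess_case(volume, extract_lung_mask(volume, lungseg_params),
                          mask=None, params=preprocess_params)
    probs = model.cascade_forward(pre.image.voxels[np.newaxis])
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    (h0, h1), (w0, w1), (d0, d1) = pre.crop_box
    crop_shape = (h1 - h0, w1 - w0, d1 - d0)
    back = resize_nearest(labels, crop_shape)
    full = np.zeros(pre.original_shape, dtype=np.uint8)
    full[h0:h1, w0:w1, d0:d1] = back
    return BinaryMask3D(voxels=full, spacing=volume.spacing, affine=volume.affine)
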