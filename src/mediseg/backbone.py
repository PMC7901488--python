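"""3D residual U-Net backbone with attention-gated skip connections.

Encoder: residual blocks (two 3x3x3 conv–instance-norm–ReLU units plus an
identity or 1x1x1-projection shortcut) interleaved with stride-2
convolutions that exactly halve every spatial dim.  Decoder: trilinear
doubling followed by a 1x1x1 channel projection, concatenation with the
(optionally attention-gated) encoder skip, and another residual block.  A
final 1x1x1 convolution maps to class logits at the input's full spatial
resolution; softmax over classes yields the probability map.

The attention gate is additive: the skip feature x is projected to an
intermediate width at the gating signal's (coarser) grid by a stride-2
1x1x1 convolution, summed with a 1x1x1 projection of the gating signal g,
passed through ReLU, reduced to one channel, squashed by a sigmoid into
attention coefficients alpha in [0,1], trilinearly upsampled to x's grid,
and multiplied element-wise into x.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .nn.layers import (
    Conv3d,
    InstanceNorm3d,
    Module,
    relu,
    relu_backward,
    sigmoid,
    softmax_channels,
)
from .resample import resize_linear, resize_linear_adjoint


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of one backbone stage."""

    in_channels: int = 1
    base_channels: int = 32
    num_levels: int = 4
    channel_growth: int = 2
    num_classes: int = 2
    use_attention: bool = True
    conv_kernel: int = 3

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.num_levels < 2:
            raise ValueError("num_levels must be >= 2")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth ** l for l in range(self.num_levels)]

    @property
    def divisor(self) -> int:
        return 2 ** (self.num_levels - 1)

    def validate_shape(self, spatial: tuple[int, int, int]) -> None:
        for ax, s in zip("HWD", spatial):
            if s % self.divisor:
                raise ValueError(
                    f"spatial dim {s} on axis {ax} is not divisible by "
                    f"2^(num_levels-1) = {self.divisor}"
                )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "BackboneConfig":
        return cls(**yaml.safe_load(text))


class ResidualBlock(Module):
    """out = shortcut(x) + F(x), F = conv-norm-relu-conv-norm."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3) -> None:
        super().__init__()
        self.conv1 = self.add("conv1", Conv3d(cin, cout, kernel, rng=rng))
        self.n1 = self.add("n1", InstanceNorm3d(cout))
        self.conv2 = self.add("conv2", Conv3d(cout, cout, kernel, rng=rng))
        self.n2 = self.add("n2", InstanceNorm3d(cout))
        self.proj = None
        if cin != cout:
            self.proj = self.add("proj", Conv3d(cin, cout, 1, rng=rng))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.n1.forward(self.conv1.forward(x))
        h = relu(a)
        f = self.n2.forward(self.conv2.forward(h))
        s = self.proj.forward(x) if self.proj is not None else x
        self._cache = a
        return s + f

    def backward(self, dout: np.ndarray) -> np.ndarray:
        a = self._cache
        dh = self.conv2.backward(self.n2.backward(dout))
        da = relu_backward(dh, a)
        dx = self.conv1.backward(self.n1.backward(da))
        if self.proj is not None:
            dx = dx + self.proj.backward(dout)
        else:
            dx = dx + dout
        return dx


class Downsample(Module):
    """Stride-2 convolution halving every spatial dim."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3) -> None:
        super().__init__()
        self.conv = self.add("conv", Conv3d(cin, cout, kernel, stride=2, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.conv.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(dout)


class Upsample(Module):
    """Trilinear doubling followed by a 1x1x1 channel projection."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = self.add("conv", Conv3d(cin, cout, 1, rng=rng))
        self._in_spatial = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_spatial = x.shape[1:]
        up = resize_linear(x, tuple(2 * s for s in x.shape[1:]))
        return self.conv.forward(up)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(dout)
        return resize_linear_adjoint(dup, self._in_spatial).astype(dout.dtype, copy=False)


class AttentionGate(Module):
    """Additive attention gate: x_hat = x * alpha, alpha in [0, 1].

    ``x`` is the encoder skip at the fine grid; ``g`` the gating signal
    from the coarser decoder level (half of x's spatial extent).
    """

    def __init__(self, ch_x: int, ch_g: int, rng: np.random.Generator,
                 inter_channels: int | None = None) -> None:
        super().__init__()
        f_int = inter_channels or max(ch_x // 2, 1)
        self.theta = self.add("theta", Conv3d(ch_x, f_int, 1, stride=2, rng=rng))
        self.phi = self.add("phi", Conv3d(ch_g, f_int, 1, rng=rng))
        self.psi = self.add("psi", Conv3d(f_int, 1, 1, rng=rng))
        self._cache = None

    def forward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        if tuple(2 * s for s in g.shape[1:]) != x.shape[1:]:
            raise ValueError(
                f"gating signal grid {g.shape[1:]} is not half of skip grid {x.shape[1:]}"
            )
        t = self.theta.forward(x)
        p = self.phi.forward(g)
        q = t + p
        a = relu(q)
        s = sigmoid(self.psi.forward(a))
        alpha = resize_linear(s, x.shape[1:])
        self._cache = (x, q, s, alpha)
        return x * alpha

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, q, s, alpha = self._cache
        dx = dout * alpha
        dalpha = (dout * x).sum(axis=0, keepdims=True)
        ds = resize_linear_adjoint(dalpha, s.shape[1:]).astype(dout.dtype, copy=False)
        dpsi_out = ds * s * (1.0 - s)
        da = self.psi.backward(dpsi_out)
        dq = relu_backward(da, q)
        dg = self.phi.backward(dq)
        dx = dx + self.theta.backward(dq)
        return dx, dg


class Backbone(Module):
    """Residual 3D U-Net producing class logits at input resolution."""

    def __init__(self, config: BackboneConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        k = config.conv_kernel

        self.stem = self.add("stem", Conv3d(config.in_channels, ch[0], k, rng=rng))
        self.enc = [self.add(f"enc{l}", ResidualBlock(ch[l], ch[l], rng, k))
                    for l in range(config.num_levels - 1)]
        self.down = [self.add(f"down{l}", Downsample(ch[l], ch[l + 1], rng, k))
                     for l in range(config.num_levels - 1)]
        self.bottom = self.add("bottom", ResidualBlock(ch[-1], ch[-1], rng, k))

        self.up, self.att, self.dec = [], [], []
        for l in range(config.num_levels - 2, -1, -1):
            self.up.append(self.add(f"up{l}", Upsample(ch[l + 1], ch[l], rng)))
            if config.use_attention:
                self.att.append(self.add(f"att{l}", AttentionGate(ch[l], ch[l + 1], rng)))
            else:
                self.att.append(None)
            self.dec.append(self.add(f"dec{l}", ResidualBlock(2 * ch[l], ch[l], rng, k)))
        self.head = self.add("head", Conv3d(ch[0], config.num_classes, 1, rng=rng))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(in_channels, H, W, D) -> (num_classes, H, W, D) logits."""
        if x.ndim != 4 or x.shape[0] != self.config.in_channels:
            raise ValueError(f"expected ({self.config.in_channels}, H, W, D) input, got {x.shape}")
        self.config.validate_shape(x.shape[1:])
        x = np.ascontiguousarray(x, dtype=self.dtype)

        h = self.stem.forward(x)
        skips = []
        for enc, down in zip(self.enc, self.down):
            h = enc.forward(h)
            skips.append(h)
            h = down.forward(h)
        h = self.bottom.forward(h)

        split_channels = []
        for i, (up, att, dec) in enumerate(zip(self.up, self.att, self.dec)):
            skip = skips[-(i + 1)]
            gated = att.forward(skip, h) if att is not None else skip
            u = up.forward(h)
            h = dec.forward(np.concatenate([u, gated], axis=0))
            split_channels.append(u.shape[0])
        self._split = split_channels
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        dskips = [None] * len(self.enc)
        for i in range(len(self.dec) - 1, -1, -1):
            dcat = self.dec[i].backward(dh)
            cu = self._split[i]
            du, dgated = dcat[:cu], dcat[cu:]
            dh = self.up[i].backward(du)
            if self.att[i] is not None:
                dskip, dg = self.att[i].backward(dgated)
                dh = dh + dg
            else:
                dskip = dgated
            dskips[len(self.enc) - 1 - i] = dskip
        dh = self.bottom.backward(dh)
        for l in range(len(self.enc) - 1, -1, -1):
            dh = self.down[l].backward(dh)
            dh = dh + dskips[l]
            dh = self.enc[l].backward(dh)
        return self.stem.backward(dh)


def backbone_forward(image: np.ndarray, config: BackboneConfig, seed: int = 0,
                     model: Backbone | None = None) -> np.ndarray:
    """Run an image through a (fresh or given) backbone; returns the
    softmax probability map, shape (num_classes, H, W, D)."""
    if image.ndim == 3:
        image = image[np.newaxis]
    net = model if model is not None else Backbone(config, seed=seed)
    logits = net.forward(image)
    return softmax_channels(logits.astype(np.float64))
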