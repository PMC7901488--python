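"""Layers: 3D convolution (im2col), instance norm, activations.

Every layer caches what its backward pass needs during forward, returns
the input gradient from ``backward`` and accumulates parameter gradients
in ``self.grads``.  Parameters are float32; gradient math runs in the
input dtype.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Module:
    """Base class: a parameter dict, a gradient dict, and child modules.

    Children register in construction order, which makes parameter
    traversal (and hence optimizer state and checkpoints) deterministic.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._children: list[tuple[str, Module]] = []

    def add(self, name: str, child: "Module") -> "Module":
        self._children.append((name, child))
        return child

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children:
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self):
        for path, mod in self.named_modules():
            for key in mod.params:
                yield (f"{path}.{key}" if path else key), mod, key

    def zero_grad(self) -> None:
        for _, mod, key in self.named_parameters():
            mod.grads[key] = np.zeros_like(mod.params[key])

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: mod.params[key].copy() for name, mod, key in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: (mod, key) for name, mod, key in self.named_parameters()}
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        for name, (mod, key) in own.items():
            arr = np.asarray(state[name], dtype=mod.params[key].dtype)
            if arr.shape != mod.params[key].shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {mod.params[key].shape}")
            mod.params[key] = arr.copy()

    def num_parameters(self) -> int:
        return sum(mod.params[key].size for _, mod, key in self.named_parameters())

    def to_dtype(self, dtype) -> "Module":
        """Convert every parameter (e.g. to float64 for gradient checks)."""
        for _, mod, key in self.named_parameters():
            mod.params[key] = mod.params[key].astype(dtype)
        return self

    @property
    def dtype(self):
        for _, mod, key in self.named_parameters():
            return mod.params[key].dtype
        return np.float32


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(C,H,W,D) -> (N_out, C*k^3) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    v = v[:, ::stride, ::stride, ::stride]
    c, ho, wo, do = v.shape[:4]
    cols = v.transpose(1, 2, 3, 0, 4, 5, 6).reshape(ho * wo * do, c * k ** 3)
    return np.ascontiguousarray(cols)


class Conv3d(Module):
    """3D convolution with isotropic kernel, 'same'-style padding.

    kernel 3, stride 1 preserves spatial shape; kernel 3, stride 2 exactly
    halves even spatial dims; kernel 1 is a per-voxel channel projection.
    Weights use Kaiming fan-in initialization from the supplied generator.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel, stride
        self.pad = kernel // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.params["w"] = rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel, kernel)).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((s + 2 * self.pad - self.k) // self.stride + 1 for s in spatial)  # type: ignore[return-value]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[0]}")
        if self.stride == 2:
            for ax, s in zip("HWD", x.shape[1:]):
                if s % 2:
                    raise ValueError(f"cannot halve odd spatial dim {s} on axis {ax}")
        cols = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.params["w"].reshape(self.cout, -1)
        out = cols @ w2.T + self.params["b"]
        spatial = self.out_shape(x.shape[1:])
        self._cache = (cols, x.shape[1:])
        return out.reshape(*spatial, self.cout).transpose(3, 0, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, in_spatial = self._cache
        dflat = dout.transpose(1, 2, 3, 0).reshape(-1, self.cout)
        self.grads["w"] = self.grads.get("w", 0) + (dflat.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] = self.grads.get("b", 0) + dflat.sum(axis=0)

        if self.k == 1 and self.stride == 1:
            w2 = self.params["w"].reshape(self.cout, self.cin)
            dx = (dflat @ w2).reshape(*dout.shape[1:], self.cin).transpose(3, 0, 1, 2)
            return np.ascontiguousarray(dx)

        # transposed convolution: dilate dout to the input grid, correlate
        # with the spatially flipped kernel, channels swapped
        if self.stride == 2:
            dz = np.zeros((self.cout, *in_spatial), dtype=dout.dtype)
            dz[:, ::2, ::2, ::2] = dout
        else:
            dz = dout
        w_rot = self.params["w"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols_d = _im2col(dz, self.k, 1, self.pad)
        dx = cols_d @ w_rot.reshape(self.cin, -1).T
        return np.ascontiguousarray(dx.reshape(*in_spatial, self.cin).transpose(3, 0, 1, 2))


class InstanceNorm3d(Module):
    """Per-channel normalization over the spatial axes, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.params["gamma"][:, None, None, None]
        b = self.params["beta"][:, None, None, None]
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        ax = (1, 2, 3)
        n = xhat[0].size
        self.grads["gamma"] = self.grads.get("gamma", 0) + (dout * xhat).sum(axis=ax)
        self.grads["beta"] = self.grads.get("beta", 0) + dout.sum(axis=ax)
        g = self.params["gamma"][:, None, None, None]
        dxhat = dout * g
        dx = (inv / n) * (n * dxhat
                          - dxhat.sum(axis=ax, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=ax, keepdims=True))
        return dx.astype(dout.dtype, copy=False)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over axis 0 (classes) of a (K, H, W, D) logit field."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)
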