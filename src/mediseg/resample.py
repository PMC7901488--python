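"""Separable linear / nearest-neighbour resampling with exact adjoints.

Resizing is expressed as one interpolation matrix per axis (each row has
at most two non-zeros), applied by tensor contraction.  This gives three
things a generic zoom routine does not: exact output shapes, a closed-form
transpose (needed for backpropagation through in-network resampling), and
bit-reproducible results.

Coordinate convention: output sample ``o`` maps to input coordinate
``(o + 0.5) * n_in / n_out - 0.5`` (pixel centres, no corner alignment),
clipped to the valid range.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=256)
def linear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix."""
    if n_in < 1 or n_out < 1:
        raise ValueError("axis lengths must be >= 1")
    M = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    i0 = np.floor(pos).astype(int)
    i0 = np.minimum(i0, n_in - 2)
    w = pos - i0
    M[np.arange(n_out), i0] = 1.0 - w
    M[np.arange(n_out), i0 + 1] = w
    return M


@lru_cache(maxsize=256)
def nearest_index(n_in: int, n_out: int) -> np.ndarray:
    """Index map for nearest-neighbour resampling along one axis."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    return np.clip(np.round(pos), 0, n_in - 1).astype(int)


def _apply_axis(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(arr, axis, -1)
    out = moved @ M.T.astype(arr.dtype, copy=False)
    return np.moveaxis(out, -1, axis)


def resize_linear(arr: np.ndarray, shape: tuple[int, ...], axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Trilinear (separable linear) resize of ``axes`` (default: last 3)."""
    if axes is None:
        axes = tuple(range(arr.ndim - len(shape), arr.ndim))
    if len(axes) != len(shape):
        raise ValueError("shape and axes length mismatch")
    out = arr
    for ax, n_out in zip(axes, shape):
        out = _apply_axis(out, linear_matrix(out.shape[ax], n_out), ax)
    return out


def resize_linear_adjoint(grad: np.ndarray, in_shape: tuple[int, ...], axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Transpose of :func:`resize_linear` for gradient propagation.

    ``in_shape`` is the spatial shape of the *forward* input whose gradient
    is wanted; ``grad`` has the forward output's spatial shape on ``axes``.
    """
    if axes is None:
        axes = tuple(range(grad.ndim - len(in_shape), grad.ndim))
    out = grad
    for ax, n_in in zip(axes, in_shape):
        out = _apply_axis(out, linear_matrix(n_in, out.shape[ax]).T, ax)
    return out


def resize_nearest(arr: np.ndarray, shape: tuple[int, ...], axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Nearest-neighbour resize; preserves the input's value set exactly."""
    if axes is None:
        axes = tuple(range(arr.ndim - len(shape), arr.ndim))
    out = arr
    for ax, n_out in zip(axes, shape):
        idx = nearest_index(out.shape[ax], n_out)
        out = np.take(out, idx, axis=ax)
    return out
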