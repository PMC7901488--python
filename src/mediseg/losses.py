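"""Weighted cross-entropy loss and the squared-denominator Dice metric.

The training loss is the sum over voxels of the weighted negative log
probability of the true class,

    E = - sum_x w(x) * log p_{k(x)}(x),

with per-voxel weights w (default 1).  Probabilities are clipped at 1e-7
before the logarithm.

The evaluation metric is the Dice coefficient in its squared-denominator
form,

    D = 2 * sum_i p_i g_i / (sum_i p_i^2 + sum_i g_i^2),

which on binary inputs coincides with the classical 2|A∩B|/(|A|+|B|).
When both fields are empty the quotient is 0/0 and D is defined as 1
(perfect agreement on emptiness).
"""

from __future__ import annotations

import numpy as np

from .ct_io import BinaryMask3D
from .resample import resize_nearest

PROB_EPS = 1e-7


def _as_array(x) -> np.ndarray:
    if isinstance(x, BinaryMask3D):
        return x.voxels
    return np.asarray(x)


def cross_entropy_loss(pred: np.ndarray, target, weights=None) -> float:
    """Summed weighted cross-entropy of a probability map vs a {0,1} target.

    Parameters
    ----------
    pred : (K, ...) array of per-class probabilities (K >= 2), or a (...)
        array of foreground probabilities treated as the two-class map
        [1-p, p].
    target : (...) array or BinaryMask3D with integer class indices.
    weights : optional (...) array of nonnegative per-voxel weights.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = _as_array(target).astype(np.int64)
    if p.shape == t.shape:
        p = np.stack([1.0 - p, p], axis=0)
    if p.shape[1:] != t.shape:
        raise ValueError(f"prediction spatial shape {p.shape[1:]} != target shape {t.shape}")
    if t.min() < 0 or t.max() >= p.shape[0]:
        raise ValueError("target contains class indices outside the prediction's classes")
    if weights is None:
        w = np.ones(t.shape, dtype=np.float64)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != t.shape:
            raise ValueError(f"weights shape {w.shape} != target shape {t.shape}")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    p_true = np.take_along_axis(p, t[np.newaxis], axis=0)[0]
    return float(-(w * np.log(np.clip(p_true, PROB_EPS, None))).sum())


def dice_coefficient(pred, gt) -> float:
    """Squared-denominator Dice between a prediction and a binary truth.

    ``pred`` may be a binary mask, a foreground-probability field of the
    truth's shape, or a (K, ...) probability map (foreground = class 1).
    """
    p = _as_array(pred).astype(np.float64)
    g = _as_array(gt).astype(np.float64)
    if p.ndim == g.ndim + 1:
        p = p[1]
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    num = 2.0 * float((p * g).sum())
    den = float((p * p).sum() + (g * g).sum())
    if den == 0.0:
        return 1.0
    return num / den


def cascade_training_loss(stage1_pred, stage2_pred, target, weights=None) -> float:
    """Equal-weight sum of the coarse and fine cross-entropy terms.

    The stage-1 term is evaluated on the target (and weights) downsampled
    by nearest neighbour to the coarse prediction's grid.
    """
    p1 = np.asarray(stage1_pred, dtype=np.float64)
    t = _as_array(target)
    coarse_shape = p1.shape[1:] if p1.ndim == t.ndim + 1 else p1.shape
    t1 = resize_nearest(t, coarse_shape)
    w1 = None if weights is None else resize_nearest(np.asarray(weights), coarse_shape)
    return cross_entropy_loss(p1, t1, w1) + cross_entropy_loss(stage2_pred, target, weights)


def class_weight_map(target, class_weights) -> np.ndarray:
    """Per-voxel weight map w(x) = class_weights[k(x)]."""
    t = _as_array(target).astype(np.int64)
    cw = np.asarray(class_weights, dtype=np.float64)
    return cw[t]
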