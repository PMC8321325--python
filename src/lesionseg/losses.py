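"""Class-balanced cross-entropy and the joint two-task objective.

For one image with ground truth ``y`` (N pixels, Npos foreground, Nneg
background) and predicted probabilities ``h``::

    l = -(1/N) * sum_n [ w1 * y_n * log h_n  +  w0 * (1 - y_n) * log(1 - h_n) ]

with inverse-class-frequency weights ``w1 = Nneg/N`` (foreground term) and
``w0 = Npos/N`` (background term), so the rarer class carries the larger
weight and ``w0 + w1 = 1``.  Weights are recomputed per image; a batch loss
is the mean of per-image losses.

The joint objective weights the two tasks as ``L = alpha * L_seg + L_edge``;
the default ``alpha = 0.05`` scales the segmentation term so both losses sit
in a similar numeric range during training (the edge target is far sparser,
so its balanced loss runs larger).
"""

from __future__ import annotations

import numpy as np

from .nn.autograd import Tensor, _make

EPS = 1e-7


def class_balance_weights(target: np.ndarray) -> tuple[float, float]:
    """Return ``(w1, w0)`` = (Nneg/N, Npos/N) for a binary target."""
    t = np.asarray(target)
    n = t.size
    npos = float(np.count_nonzero(t))
    return (n - npos) / n, npos / n


def _per_image_view(arr: np.ndarray) -> np.ndarray:
    """Collapse any of (H,W), (N,H,W), (N,1,H,W) to (N, pixels)."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[None]
    elif a.ndim == 4:
        if a.shape[1] != 1:
            raise ValueError(f"expected single-channel maps, got {a.shape}")
        a = a[:, 0]
    return a.reshape(a.shape[0], -1)


def _balanced_bce_value_grad(pred: np.ndarray, target: np.ndarray, eps: float):
    h = _per_image_view(pred).astype(np.float64)
    y = _per_image_view(target).astype(np.float64)
    if h.shape != y.shape:
        raise ValueError(f"prediction {pred.shape} and target {target.shape} differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("target must be strictly binary")
    k, n = y.shape
    npos = y.sum(axis=1, keepdims=True)
    w1 = (n - npos) / n  # foreground weight
    w0 = npos / n        # background weight
    clamped = np.clip(h, eps, 1.0 - eps)
    per_image = -(w1 * y * np.log(clamped) + w0 * (1.0 - y) * np.log1p(-clamped)).sum(axis=1) / n
    loss = float(per_image.mean())
    inside = (h > eps) & (h < 1.0 - eps)  # clamp kills the gradient outside
    grad = -(w1 * y / clamped - w0 * (1.0 - y) / (1.0 - clamped)) / (k * n)
    grad = np.where(inside, grad, 0.0)
    return loss, grad.reshape(np.shape(pred))


def balanced_bce(pred, target, eps: float = EPS):
    """Class-balanced BCE; accepts an autograd ``Tensor`` or a plain array.

    Degenerate targets (all foreground or all background) are well defined:
    the absent class has weight zero and contributes no pixels.
    """
    target = np.asarray(getattr(target, "data", target))
    if isinstance(pred, Tensor):
        loss, grad = _balanced_bce_value_grad(pred.data, target, eps)
        return _make(np.float64(loss), [(pred, lambda g: g * grad)])
    loss, _ = _balanced_bce_value_grad(np.asarray(pred), target, eps)
    return loss


def joint_loss(l_seg, l_edge, alpha: float = 0.05):
    """``L = alpha * l_seg + l_edge`` — works on floats or autograd scalars."""
    if isinstance(l_seg, Tensor) or isinstance(l_edge, Tensor):
        return alpha * (l_seg if isinstance(l_seg, Tensor) else Tensor(l_seg)) + l_edge
    return alpha * l_seg + l_edge
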