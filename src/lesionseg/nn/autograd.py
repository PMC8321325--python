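"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each op returns a :class:`Tensor`
holding the forward value plus vector-Jacobian-product closures back to its
parents.  Only the operations the lesion-segmentation network needs are
implemented (dense conv2d with stride/dilation, batch norm, max pooling,
separable linear resampling, elementwise nonlinearities, concatenation).
Gradient correctness is established by finite-difference checks in the test
suite rather than by symbolic derivation at run time.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray with an optional gradient and backward references."""

    __slots__ = ("data", "grad", "requires_grad", "_backrefs")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backrefs = []  # list of (parent Tensor, vjp callable)

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be ~100s of nodes deep)
        topo, stack, seen = [], [(self, False)], set()
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._backrefs:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node._backrefs:
                pg = vjp(g)
                if pg.dtype != parent.data.dtype:
                    pg = pg.astype(parent.data.dtype)
                parent.grad = pg if parent.grad is None else parent.grad + pg

    # -- light operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents_vjps) -> Tensor:
    """Build an op result wired to the parents that need gradients."""
    if _GRAD_ENABLED:
        refs = [(p, fn) for p, fn in parents_vjps
                if isinstance(p, Tensor) and p.requires_grad]
    else:
        refs = []
    out = Tensor(data, requires_grad=bool(refs))
    out._backrefs = refs
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(g, b.data.shape))],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(g * a.data, b.data.shape))],
    )


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _make(np.where(mask, x.data, 0), [(x, lambda g: g * mask)])


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    d = x.data
    s = np.empty_like(d)
    pos = d >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ex = np.exp(d[~pos])
    s[~pos] = ex / (1.0 + ex)
    return _make(s, [(x, lambda g: g * s * (1.0 - s))])


def mean(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n = x.data.size
    return _make(x.data.mean(), [(x, lambda g: np.full_like(x.data, g / n))])


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def make_vjp(i):
        return lambda g: np.split(g, splits, axis=axis)[i]

    return _make(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding/dilation.

    Implemented as a sum of per-kernel-offset channel matmuls
    (shift-and-matmul), which avoids materialising a full im2col buffer.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    s, p, d = stride, padding, dilation
    Ho = (H + 2 * p - d * (kh - 1) - 1) // s + 1
    Wo = (W + 2 * p - d * (kw - 1) - 1) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    def offset_slice(arr, i, j):
        return arr[:, :, i * d: i * d + (Ho - 1) * s + 1: s,
                   j * d: j * d + (Wo - 1) * s + 1: s]

    y = np.zeros((N, O, Ho, Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = offset_slice(xp, i, j)
            # (O,C) x (N,C,Ho,Wo) -> (O,N,Ho,Wo)
            y += np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        y += b.data[None, :, None, None]

    def vjp_x(g):
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                # (N,O,Ho,Wo) x (O,C) -> (N,C,Ho,Wo)
                t = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
                offset_slice(gxp, i, j)[...] += t
        return gxp[:, :, p:p + H, p:p + W] if p else gxp

    def vjp_w(g):
        gw = np.empty_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = offset_slice(xp, i, j)
                gw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
        return gw

    parents = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return _make(y, parents)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch norm; updates running statistics in place when training."""
    x = as_tensor(x)
    d = x.data
    if training:
        mu = d.mean(axis=(0, 2, 3))
        var = d.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (d - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    m = d.shape[0] * d.shape[2] * d.shape[3]

    def vjp_x(g):
        gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if not training:
            return g * gs
        g_mean = g.mean(axis=(0, 2, 3))[None, :, None, None]
        gx_mean = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / m
        return gs * (g - g_mean - xhat * gx_mean)

    return _make(y, [
        (x, vjp_x),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    ])


# ---------------------------------------------------------------------------
# pooling and resampling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(N, C, Ho, Wo, k * k)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def vjp(g):
        gxp = np.zeros((N, C, Hp, Wp), dtype=g.dtype)
        n, c, io, jo = np.indices((N, C, Ho, Wo), sparse=False)
        ii = io * s + arg // k
        jj = jo * s + arg % k
        np.add.at(gxp, (n, c, ii, jj), g)
        return gxp[:, :, p:p + H, p:p + W] if p else gxp

    return _make(y, [(x, vjp)])


@lru_cache(maxsize=256)
def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centres)."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        M[o, i0] += 1.0 - t
        M[o, i1] += t
    return M


@lru_cache(maxsize=256)
def _adaptive_avg_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D adaptive average-pooling matrix with floor/ceil bin edges."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        lo = (o * n_in) // n_out
        hi = -(-(o + 1) * n_in // n_out)  # ceil division
        M[o, lo:hi] = 1.0 / (hi - lo)
    return M


def _apply_separable(d: np.ndarray, Rh: np.ndarray, Rw: np.ndarray) -> np.ndarray:
    t = np.tensordot(d, Rw, axes=([3], [1]))          # (N,C,H,Wo)
    t = np.tensordot(t, Rh, axes=([2], [1]))          # (N,C,Wo,Ho)
    return np.ascontiguousarray(t.transpose(0, 1, 3, 2))


def _resize_linear(x: Tensor, Rh: np.ndarray, Rw: np.ndarray) -> Tensor:
    x = as_tensor(x)
    y = _apply_separable(x.data, Rh, Rw)
    return _make(y, [(x, lambda g: _apply_separable(g, Rh.T, Rw.T))])


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (exact linear operator)."""
    h, w = x.data.shape[2], x.data.shape[3]
    if (h, w) == (out_h, out_w):
        return as_tensor(x) if not isinstance(x, Tensor) else x
    return _resize_linear(x, _bilinear_matrix(h, out_h), _bilinear_matrix(w, out_w))


def adaptive_avg_pool2d(x: Tensor, bins: int) -> Tensor:
    h, w = x.data.shape[2], x.data.shape[3]
    return _resize_linear(x, _adaptive_avg_matrix(h, bins), _adaptive_avg_matrix(w, bins))
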