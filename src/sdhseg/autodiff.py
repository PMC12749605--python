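"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for 2-D encoder-decoder segmentation
networks and the boundary-loss surrogate: broadcasting arithmetic, matmul,
element-wise non-linearities, stride-1 convolutions (im2col, BLAS-backed),
2x2 max pooling, nearest-neighbour upsampling, 3x3 min pooling with
zero padding, concatenation, slicing and reductions.

Gradients are accumulated by ``Tensor.backward()`` over a topologically
sorted tape. Non-smooth primitives (relu, max/min pooling, abs) propagate a
valid subgradient, with ties resolved deterministically towards the first
attaining element.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "relu",
    "softplus",
    "exp",
    "log",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "minpool3x3",
    "where_const",
]

_DEFAULT_DTYPE = np.float32
_SCALARS = (int, float, np.integer, np.floating)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        if isinstance(data, np.ndarray):
            self.data = data
        else:
            arr = np.asarray(data)  # np scalars (e.g. from reductions) keep their dtype
            self.data = arr if np.issubdtype(arr.dtype, np.floating) else arr.astype(_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp

    # -- bookkeeping -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                for parent, g in node._vjp(node.grad):
                    if not parent.requires_grad:
                        continue
                    if parent.grad is None:
                        parent.grad = g.astype(parent.data.dtype, copy=False)
                    else:
                        parent.grad = parent.grad + g

    # -- arithmetic --------------------------------------------------------
    # Plain python/numpy scalars take a fast path that leans on numpy's weak
    # scalar promotion, so they neither widen float32 graphs nor round
    # float64 graphs down.

    def __add__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor(self.data + other, _parents=(self,), _vjp=lambda g: ((self, g),))
        other = as_tensor(other)
        out_data = self.data + other.data

        def vjp(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _vjp=vjp)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: ((self, -g),))

    def __sub__(self, other):
        if isinstance(other, _SCALARS):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, _SCALARS):
            return Tensor(self.data * other, _parents=(self,), _vjp=lambda g: ((self, g * other),))
        other = as_tensor(other)
        out_data = self.data * other.data

        def vjp(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _vjp=vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, _SCALARS):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def vjp(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _vjp=vjp)

    def __rtruediv__(self, other):
        if isinstance(other, _SCALARS):
            inv = self**-1.0
            return inv * other
        return as_tensor(other) / self

    def __pow__(self, k: float):
        out_data = self.data**k

        def vjp(g):
            return ((self, g * k * self.data ** (k - 1)),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def vjp(g):
            return ((self, g @ other.data.T), (other, self.data.T @ g))

        return Tensor(out_data, _parents=(self, other), _vjp=vjp)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def vjp(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    # -- reductions / reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                g_arr = np.expand_dims(g_arr, axis)
            return ((self, np.broadcast_to(g_arr, self.data.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def vjp(g):
            return ((self, g.reshape(orig)),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def transpose(self, *axes):
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def vjp(g):
            return ((self, g.transpose(*inv)),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    # -- element-wise non-linearities ---------------------------------------

    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)  # subgradient 0 at 0

        def vjp(g):
            return ((self, g * sign),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def clip_min(self, lo: float):
        """max(x, lo) with subgradient 1 where x > lo."""
        out_data = np.maximum(self.data, lo)
        mask = (self.data > lo).astype(self.data.dtype)

        def vjp(g):
            return ((self, g * mask),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def clip_max(self, hi: float):
        out_data = np.minimum(self.data, hi)
        mask = (self.data < hi).astype(self.data.dtype)

        def vjp(g):
            return ((self, g * mask),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)


def as_tensor(x) -> Tensor:
    """Wrap ``x`` as a constant Tensor; floating dtypes are preserved,
    anything else is cast to float32."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(_DEFAULT_DTYPE)
    return Tensor(arr)


# -- functional primitives ---------------------------------------------------


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def vjp(g):
        return ((x, g * out_data),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def vjp(g):
        return ((x, g / x.data),)

    return Tensor(np.log(x.data), _parents=(x,), _vjp=vjp)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # overflow-free

    def vjp(g):
        return ((x, g * out_data * (1.0 - out_data)),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def vjp(g):
        return ((x, g * mask),)

    return Tensor(x.data * mask, _parents=(x,), _vjp=vjp)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) computed stably as max(x,0) + log1p(exp(-|x|))."""
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0) + np.log1p(np.exp(-np.abs(x.data)))
    sig = 0.5 * (np.tanh(0.5 * x.data) + 1.0)

    def vjp(g):
        return ((x, g * sig),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out_data, _parents=tuple(tensors), _vjp=vjp)


def where_const(cond: np.ndarray, x: Tensor, y: Tensor) -> Tensor:
    """Select between two tensors by a constant boolean mask."""
    x, y = as_tensor(x), as_tensor(y)
    cond = np.asarray(cond, dtype=bool)
    out_data = np.where(cond, x.data, y.data)

    def vjp(g):
        return ((x, _unbroadcast(g * cond, x.data.shape)),
                (y, _unbroadcast(g * (~cond), y.data.shape)))

    return Tensor(out_data, _parents=(x, y), _vjp=vjp)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,). im2col + matmul forward,
    closed-form col2im backward (9 shifted adds for a 3x3 kernel).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(f, c * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    out_data = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    def vjp(g):
        gy = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
        grads = []
        if x.requires_grad:
            dcols = gy @ wmat  # (N*Ho*Wo, C*kh*kw)
            dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j]
            dx = dxp[:, :, padding:padding + h, padding:padding + wid] if padding else dxp
            grads.append((x, dx))
        if w.requires_grad:
            dw = (gy.T @ cols).reshape(f, c, kh, kw)
            grads.append((w, dw))
        if b is not None and b.requires_grad:
            grads.append((b, gy.sum(axis=0)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _vjp=vjp)


def maxpool2x2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2 max pooling; ties route gradient to the first max."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return ((x, dx),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def vjp(g):
        dx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        return ((x, dx),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)


def minpool3x3(x: Tensor) -> Tensor:
    """3x3 min pooling with zero padding (frame exterior treated as 0).

    Operates on (H, W) maps. Ties route the subgradient to the first
    attaining in-frame element; a padding minimum contributes no gradient.
    """
    x = as_tensor(x)
    h, w = x.data.shape
    xp = np.pad(x.data, 1, mode="constant", constant_values=0.0)
    win = sliding_window_view(xp, (3, 3))  # H,W,3,3
    flat = win.reshape(h, w, 9)
    idx = flat.argmin(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        dxp = np.zeros_like(xp)
        rows = idx // 3
        cols = idx % 3
        rr = np.arange(h)[:, None] + rows
        cc = np.arange(w)[None, :] + cols
        np.add.at(dxp, (rr, cc), g)
        return ((x, dxp[1:-1, 1:-1]),)

    return Tensor(out_data, _parents=(x,), _vjp=vjp)
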