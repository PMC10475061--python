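"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tensor engine sufficient for small convolutional and recurrent
networks: elementwise arithmetic with broadcasting, matmul, reductions,
shape ops, 2-D/3-D convolution (regular and depthwise), non-overlapping
max pooling, nearest-neighbour upsampling and a fused softmax
cross-entropy. Everything is float64 and CPU-only.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "relu", "sigmoid", "tanh", "exp", "log",
    "tsum", "tmean", "reshape", "transpose", "concat", "tslice", "stack",
    "conv2d", "depthwise_conv2d", "conv3d",
    "maxpool2d", "maxpool3d", "avgpool2d", "avgpool3d", "avgpool_same3d",
    "upsample_nearest2d", "softmax_cross_entropy", "softmax",
    "dropout_mask", "batch_norm_train",
    "set_default_dtype", "get_default_dtype", "default_dtype",
]

_DEFAULT_DTYPE = np.dtype(np.float64)


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)


def get_default_dtype() -> np.dtype:
    return _DEFAULT_DTYPE


@contextmanager
def default_dtype(dtype):
    """Temporarily switch the dtype given to newly created tensors.

    Training runs under float32 for speed; the float64 default keeps the
    functional ops accurate enough for 1e-6 oracle comparisons.
    """
    previous = _DEFAULT_DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(previous)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating) or arr.ndim == 0:
            # ints/bools and bare scalars adopt the engine default so that
            # float32 graphs are not silently promoted to float64
            arr = arr.astype(_DEFAULT_DTYPE)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def __getitem__(self, idx):
        return tslice(self, idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out.requires_grad = requires_grad
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, copy=True)
    else:
        t.grad = t.grad + g


# -- elementwise ------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(grad):
        _accum(a, _unbroadcast(grad, a.data.shape))
        _accum(b, _unbroadcast(grad, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(grad):
        _accum(a, _unbroadcast(grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(grad * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(grad):
        _accum(x, grad * mask)

    return _make(data, (x,), backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    data = _stable_sigmoid(x.data)

    def backward(grad):
        _accum(x, grad * data * (1.0 - data))

    return _make(data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    data = np.tanh(x.data)

    def backward(grad):
        _accum(x, grad * (1.0 - data * data))

    return _make(data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    data = np.exp(x.data)

    def backward(grad):
        _accum(x, grad * data)

    return _make(data, (x,), backward)


def log(x: Tensor) -> Tensor:
    data = np.log(x.data)

    def backward(grad):
        _accum(x, grad / x.data)

    return _make(data, (x,), backward)


def power(x: Tensor, p: float) -> Tensor:
    data = x.data ** p

    def backward(grad):
        _accum(x, grad * p * x.data ** (p - 1))

    return _make(data, (x,), backward)


# -- linear algebra / reductions / shape -------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(grad):
        _accum(a, grad @ b.data.T)
        _accum(b, a.data.T @ grad)

    return _make(data, (a, b), backward)


def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g, x.data.shape).copy())

    return _make(data, (x,), backward)


def tmean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    s = tsum(x, axis=axis, keepdims=keepdims)
    return mul(s, _as_tensor(1.0 / n))


def reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def backward(grad):
        _accum(x, grad.reshape(x.data.shape))

    return _make(data, (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    data = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        _accum(x, grad.transpose(inv))

    return _make(data, (x,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, grad[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad):
        parts = np.split(grad, len(tensors), axis=axis)
        for t, g in zip(tensors, parts):
            _accum(t, np.squeeze(g, axis=axis))

    return _make(data, tuple(tensors), backward)


def tslice(x: Tensor, idx) -> Tensor:
    data = x.data[idx]

    def backward(grad):
        g = np.zeros_like(x.data)
        np.add.at(g, idx, grad)
        _accum(x, g)

    return _make(data, (x,), backward)


# -- convolution -------------------------------------------------------------


def _pad_same_2d(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 cross-correlation.

    x: (N, C_in, H, W); w: (C_out, C_in, kh, kw); b: (C_out,) or None.
    Implemented as one BLAS matmul per kernel tap.
    """
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Ci}")
    xp = _pad_same_2d(x.data, kh, kw)
    taps = []  # contiguous (N, C, H*W) slice per tap, reused in backward
    out = np.zeros((N, Co, H * W), dtype=x.data.dtype)
    for a in range(kh):
        for bb in range(kw):
            xs = np.ascontiguousarray(
                xp[:, :, a:a + H, bb:bb + W]).reshape(N, C, H * W)
            taps.append(xs)
            out += w.data[:, :, a, bb] @ xs
    data = out.reshape(N, Co, H, W)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gr = grad.reshape(N, Co, H * W)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i, (a, bb) in enumerate(np.ndindex(kh, kw)):
                gw[:, :, a, bb] = np.einsum(
                    "noi,nci->oc", gr, taps[i], optimize=True)
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for bb in range(kw):
                    g = (w.data[:, :, a, bb].T @ gr).reshape(N, C, H, W)
                    gxp[:, :, a:a + H, bb:bb + W] += g
            ph, pw = kh // 2, kw // 2
            _accum(x, gxp[:, :, ph:ph + H, pw:pw + W])

    return _make(data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel same-padded stride-1 cross-correlation.

    x: (N, C, H, W); w: (C, kh, kw) — one kernel per input channel.
    """
    N, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"depthwise_conv2d: {C} channels but {Cw} kernels")
    xp = _pad_same_2d(x.data, kh, kw)
    out = np.zeros((N, C, H, W), dtype=x.data.dtype)
    for a in range(kh):
        for bb in range(kw):
            out += w.data[None, :, a, bb, None, None] * xp[:, :, a:a + H, bb:bb + W]
    data = out
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for a in range(kh):
                for bb in range(kw):
                    gw[:, a, bb] = (grad * xp[:, :, a:a + H, bb:bb + W]).sum(
                        axis=(0, 2, 3))
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for bb in range(kw):
                    gxp[:, :, a:a + H, bb:bb + W] += (
                        w.data[None, :, a, bb, None, None] * grad)
            ph, pw = kh // 2, kw // 2
            _accum(x, gxp[:, :, ph:ph + H, pw:pw + W])

    return _make(data, parents, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 3-D cross-correlation.

    x: (N, C_in, D, H, W); w: (C_out, C_in, kd, kh, kw).
    """
    N, C, D, H, W = x.data.shape
    Co, Ci, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv3d: input has {C} channels, kernel expects {Ci}")
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    M = D * H * W
    out = np.zeros((N, Co, M), dtype=x.data.dtype)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                xs = np.ascontiguousarray(
                    xp[:, :, a:a + D, bb:bb + H, c:c + W]).reshape(N, C, M)
                out += w.data[:, :, a, bb, c] @ xs
    data = out.reshape(N, Co, D, H, W)
    if b is not None:
        data = data + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gr = grad.reshape(N, Co, M)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        xs = np.ascontiguousarray(
                            xp[:, :, a:a + D, bb:bb + H, c:c + W]).reshape(N, C, M)
                        gw[:, :, a, bb, c] = np.einsum(
                            "noi,nci->oc", gr, xs, optimize=True)
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, grad.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        g = (w.data[:, :, a, bb, c].T @ gr).reshape(N, C, D, H, W)
                        gxp[:, :, a:a + D, bb:bb + H, c:c + W] += g
            _accum(x, gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])

    return _make(data, parents, backward)


# -- pooling / resampling ----------------------------------------------------


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"maxpool2d: dims ({H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    data = r.max(axis=(3, 5))
    mask = r == data[:, :, :, None, :, None]
    # break ties: keep only the first max in each window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // k, W // k, k * k)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(N, C, H // k, W // k, k, k).transpose(0, 1, 2, 4, 3, 5)

    def backward(grad):
        g = mask * grad[:, :, :, None, :, None]
        _accum(x, g.reshape(N, C, H, W))

    return _make(data, (x,), backward)


def maxpool3d(x: Tensor, k: tuple[int, int, int]) -> Tensor:
    kd, kh, kw = k
    N, C, D, H, W = x.data.shape
    if D % kd or H % kh or W % kw:
        raise ValueError(f"maxpool3d: dims ({D},{H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, D // kd, kd, H // kh, kh, W // kw, kw)
    data = r.max(axis=(3, 5, 7))
    mask = r == data[:, :, :, None, :, None, :, None]
    flat = mask.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        N, C, D // kd, H // kh, W // kw, kd * kh * kw)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(N, C, D // kd, H // kh, W // kw, kd, kh, kw).transpose(
        0, 1, 2, 5, 3, 6, 4, 7)

    def backward(grad):
        g = mask * grad[:, :, :, None, :, None, :, None]
        _accum(x, g.reshape(N, C, D, H, W))

    return _make(data, (x,), backward)


def avgpool2d(x: Tensor, k: int) -> Tensor:
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avgpool2d: dims ({H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    data = r.mean(axis=(3, 5))

    def backward(grad):
        g = np.broadcast_to(grad[:, :, :, None, :, None] / (k * k),
                            (N, C, H // k, k, W // k, k))
        _accum(x, g.reshape(N, C, H, W))

    return _make(data, (x,), backward)


def avgpool3d(x: Tensor, k: tuple[int, int, int]) -> Tensor:
    kd, kh, kw = k
    N, C, D, H, W = x.data.shape
    if D % kd or H % kh or W % kw:
        raise ValueError(f"avgpool3d: dims ({D},{H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, D // kd, kd, H // kh, kh, W // kw, kw)
    data = r.mean(axis=(3, 5, 7))
    n = kd * kh * kw

    def backward(grad):
        g = np.broadcast_to(grad[:, :, :, None, :, None, :, None] / n,
                            (N, C, D // kd, kd, H // kh, kh, W // kw, kw))
        _accum(x, g.reshape(N, C, D, H, W))

    return _make(data, (x,), backward)


def avgpool_same3d(x: Tensor, k: int = 3) -> Tensor:
    """Stride-1, same-padded 3-D average pooling (window k^3, zero padding)."""
    N, C, D, H, W = x.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros_like(x.data)
    for a in range(k):
        for bb in range(k):
            for c in range(k):
                out += xp[:, :, a:a + D, bb:bb + H, c:c + W]
    out /= k ** 3
    def backward(grad):
        gp = np.zeros_like(xp)
        g = grad / k ** 3
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    gp[:, :, a:a + D, bb:bb + H, c:c + W] += g
        _accum(x, gp[:, :, p:p + D, p:p + H, p:p + W])

    return _make(out, (x,), backward)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    N, C, H, W = x.data.shape

    def backward(grad):
        g = grad.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        _accum(x, g)

    return _make(data, (x,), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over all axes except axis 1.

    Returns (out, batch_mean, batch_var) where the statistics are plain
    per-channel numpy vectors for running-average bookkeeping.
    """
    axes = tuple(i for i in range(x.data.ndim) if i != 1)
    bshape = tuple(x.data.shape[1] if i == 1 else 1 for i in range(x.data.ndim))
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    g = gamma.data.reshape(bshape)
    data = g * xhat + beta.data.reshape(bshape)
    n = x.data.size // x.data.shape[1]

    def backward(grad):
        if beta.requires_grad:
            _accum(beta, grad.sum(axis=axes))
        if gamma.requires_grad:
            _accum(gamma, (grad * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = grad * g
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            _accum(x, (inv / n) * (n * dxhat - s1 - xhat * s2))

    out = _make(data, (x, gamma, beta), backward)
    return out, mean.reshape(-1), var.reshape(-1)


# -- classification head -----------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax of `logits` (N, K)."""
    labels = np.asarray(labels, dtype=np.intp)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    data = -np.mean(np.log(probs[np.arange(n), labels] + eps))

    def backward(grad):
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        _accum(logits, grad * g / n)

    return _make(data, (logits,), backward)


def dropout_mask(x: Tensor, mask: np.ndarray) -> Tensor:
    """Apply a precomputed (already scaled) dropout mask."""
    data = x.data * mask

    def backward(grad):
        _accum(x, grad * mask)

    return _make(data, (x,), backward)
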