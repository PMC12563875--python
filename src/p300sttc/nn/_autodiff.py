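"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the Transformer-CNN classifier: broadcast-aware
elementwise ops, batched matmul, softmax, reductions, valid 2-D convolution
via im2col, 2x2 max pooling, dropout and a fused softmax cross-entropy.
Gradient correctness is exercised by finite-difference tests.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "neg", "power", "matmul", "transpose",
    "reshape", "tsum", "tmean", "relu", "softmax", "conv2d_valid",
    "maxpool2x2", "dropout", "cross_entropy", "Adam",
    "default_dtype", "get_default_dtype",
]

_DEFAULT_DTYPE = np.float64


def get_default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily set the dtype new tensors are created with.

    float32 roughly halves training cost; float64 is the default and is what
    finite-difference gradient checks should use.
    """
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


class Tensor:
    """Node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seeding 1s."""
        topo, seen = [], set()

        def build(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _prev=parents if req else (),
                  _backward=backward if req else None)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(a.data**p, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(np.matmul(a.data, b.data), (a, b), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return _make(np.transpose(a.data, axes), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(gg, a.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    s = a.data - a.data.max(axis=axis, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

    return _make(s, (a,), backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """x (B, C, H, W) -> patches (B, H-kh+1, W-kw+1, C, kh, kw) as a view."""
    B, C, H, W = x.shape
    oh, ow = H - kh + 1, W - kw + 1
    s = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, oh, ow, C, kh, kw),
        strides=(s[0], s[2], s[3], s[1], s[2], s[3]),
        writeable=False,
    )


def conv2d_valid(x, w, b) -> Tensor:
    """Valid-mode 2-D convolution (cross-correlation, the CNN convention).

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,).
    Returns (B, Cout, H-kh+1, W-kw+1).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, Cin, H, W = x.shape
    Cout, _, kh, kw = w.shape
    patches = _im2col(x.data, kh, kw)  # (B, oh, ow, Cin, kh, kw)
    out = np.tensordot(patches, w.data, axes=([3, 4, 5], [1, 2, 3]))  # (B, oh, ow, Cout)
    out = np.transpose(out, (0, 3, 1, 2)) + b.data[None, :, None, None]
    oh, ow = H - kh + 1, W - kw + 1

    def backward(g):
        # g: (B, Cout, oh, ow)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(g, patches, axes=([0, 2, 3], [0, 1, 2]))  # (Cout, Cin, kh, kw)
            w._accumulate(gw)
        if x.requires_grad:
            gx = np.zeros((B, Cin, H, W), dtype=x.data.dtype)
            # scatter-add: full correlation of g with flipped kernels
            for i in range(kh):
                for j in range(kw):
                    # contribution of kernel tap (i, j): (B,oh,ow,Cin)
                    tap = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                    gx[:, :, i:i + oh, j:j + ow] += np.transpose(tap, (0, 3, 1, 2))
            x._accumulate(gx)

    return _make(out, (x, w, b), backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    oh, ow = H // 2, W // 2
    crop = x.data[:, :, : oh * 2, : ow * 2]
    blocks = crop.reshape(B, C, oh, 2, ow, 2)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]
    # break ties: keep only the first max in each 2x2 block
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, oh, ow, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(B, C, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        gb = mask * g[:, :, :, None, :, None]
        gx[:, :, : oh * 2, : ow * 2] = gb.reshape(B, C, oh * 2, ow * 2)
        x._accumulate(gx)

    return _make(out, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    x = _as_tensor(x)
    if not training or p <= 0:
        return x
    keep = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _make(x.data * keep, (x,), backward)


def cross_entropy(logits, y) -> Tensor:
    """Mean softmax cross-entropy; ``y`` is an int class-index vector."""
    logits = _as_tensor(logits)
    y = np.asarray(y, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = y.size
    loss = -logp[np.arange(n), y].mean()

    def backward(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(n), y] -= 1.0
            logits._accumulate(g * grad / n)

    return _make(loss, (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
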