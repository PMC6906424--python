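"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Everything the translation networks need — 2D convolution (im2col), instance
normalization, nearest-neighbour upsampling, the usual pointwise
nonlinearities and reductions — with exact gradients, float64 throughout, and
no threading or other nondeterminism: two runs with the same seed produce
bit-identical results on one CPU.

Tensors form a tape; ``Tensor.backward()`` on a scalar topologically sorts the
tape and accumulates gradients into ``.grad`` of every tensor with
``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "log", "abs_", "sigmoid", "tanh",
    "relu", "leaky_relu", "mean", "sum_", "conv2d", "upsample_nearest2",
    "avg_pool2", "instance_norm", "concat",
]


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience operators (constants become leaf tensors).
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._backward is not None):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bw)


def log(a: Tensor, eps: float = 1e-12) -> Tensor:
    clipped = np.maximum(a.data, eps)

    def bw(g):
        _accum(a, g / clipped)

    return _make(np.log(clipped), (a,), bw)


def abs_(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def bw(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        _accum(a, g * y * (1.0 - y))

    return _make(y, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - y * y))

    return _make(y, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(a.data > 0, 1.0, alpha)

    def bw(g):
        _accum(a, g * slope)

    return _make(a.data * slope, (a,), bw)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def bw(g):
        _accum(a, np.full_like(a.data, float(g) / n))

    return _make(a.data.mean(), (a,), bw)


def sum_(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o0, o1)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation), single sample: x (Cin, H, W),
    w (Cout, Cin, kh, kw), b (Cout,) -> (Cout, oh, ow).

    Computed as one matmul per kernel tap over shifted input slices, which
    keeps the working set small and contiguous.
    """
    Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    shifts = []
    yflat = np.zeros((Cout, oh * ow))
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xp[:, i : i + (oh - 1) * stride + 1 : stride,
                   j : j + (ow - 1) * stride + 1 : stride]
            ).reshape(Cin, oh * ow)
            shifts.append(xs)
            yflat += w.data[:, :, i, j] @ xs
    y = yflat.reshape(Cout, oh, ow) + b.data[:, None, None]

    def bw(g):
        gflat = np.ascontiguousarray(g).reshape(Cout, oh * ow)
        _accum(b, g.sum(axis=(1, 2)))
        want_dw = w.requires_grad or w._backward is not None
        want_dx = x.requires_grad or x._backward is not None
        dw = np.zeros_like(w.data) if want_dw else None
        dxp = np.zeros_like(xp) if want_dx else None
        for idx, (i, j) in enumerate((i, j) for i in range(kh) for j in range(kw)):
            if want_dw:
                dw[:, :, i, j] = gflat @ shifts[idx].T
            if want_dx:
                dxp[:, i : i + (oh - 1) * stride + 1 : stride,
                    j : j + (ow - 1) * stride + 1 : stride] += (
                    w.data[:, :, i, j].T @ gflat
                ).reshape(Cin, oh, ow)
        if want_dw:
            _accum(w, dw)
        if want_dx:
            _accum(x, dxp[:, pad : pad + H, pad : pad + W] if pad else dxp)

    return _make(y, (x, w, b), bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (C, H, W)."""
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bw(g):
        C, H2, W2 = g.shape
        _accum(x, g.reshape(C, H2 // 2, 2, W2 // 2, 2).sum(axis=(2, 4)))

    return _make(y, (x,), bw)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 of (C, H, W); H, W must be even."""
    C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    y = x.data.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def bw(g):
        _accum(x, np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0)

    return _make(y, (x,), bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of (C, H, W);
    gamma/beta have shape (C, 1, 1)."""
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    var = x.data.var(axis=(1, 2), keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    y = gamma.data * xhat + beta.data

    def bw(g):
        _accum(beta, g.sum(axis=(1, 2), keepdims=True))
        _accum(gamma, (g * xhat).sum(axis=(1, 2), keepdims=True))
        if x.requires_grad or x._backward is not None:
            gh = g * gamma.data
            m1 = gh.mean(axis=(1, 2), keepdims=True)
            m2 = (gh * xhat).mean(axis=(1, 2), keepdims=True)
            _accum(x, (gh - m1 - xhat * m2) / std)

    return _make(y, (x, gamma, beta), bw)
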