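"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation networks need: elementwise
arithmetic, log/exp/sigmoid/relu, reductions, channel concatenation,
3-D convolution (stride 1, 'same' padding, via im2col + BLAS matmul),
2x max pooling, 2x nearest-neighbour upsampling and per-channel instance
standardization. Tensors are laid out channel-last: (N, D, H, W, C).

Everything is float32 and purely numpy, so runs are bit-reproducible for a
fixed seed on the same platform.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Tuple["Tensor", ...] = (),
        backward_fn: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self.parents = parents if _grad_enabled else ()
        self.backward_fn = backward_fn if _grad_enabled else None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node.parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # operator sugar
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __neg__(self):
        return mul(self, as_tensor(np.float32(-1.0)))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


class Parameter(Tensor):
    """A learnable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)
        # parameters always participate in the graph
        self.parents = ()
        self.backward_fn = None


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a: Tensor, b: Tensor, out_data, da, db) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(da(g), a.data.shape))
        b.accumulate(_unbroadcast(db(g), b.data.shape))

    return Tensor(out_data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def div(a: Tensor, b: Tensor) -> Tensor:
    return _binary(
        a, b, a.data / b.data,
        lambda g: g / b.data,
        lambda g: -g * a.data / (b.data * b.data),
    )


def pow_const(a: Tensor, p: float) -> Tensor:
    out = a.data ** np.float32(p)

    def backward(g):
        if p == 0.0:
            return  # derivative of the constant 1
        a.accumulate(g * np.float32(p) * a.data ** np.float32(p - 1.0))

    return Tensor(out, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(g / a.data)

    return Tensor(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)

    def backward(g):
        a.accumulate(g * out)

    return Tensor(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a.accumulate(g * out * (1.0 - out))

    return Tensor(out, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a.accumulate(g * mask)

    return Tensor(np.where(mask, a.data, 0.0), (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor(out, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / out.size

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g, a.data.shape) / np.float32(n))

    return Tensor(out, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    return Tensor(out, tuple(tensors), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a.accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), (a,), backward)


# ---------------------------------------------------------------------------
# Structured ops
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """3-D convolution, stride 1, 'same' zero padding.

    x: (N, D, H, W, Cin); w: (k, k, k, Cin, Cout); b: (Cout,).
    im2col + one BLAS matmul per call.
    """
    k = w.data.shape[0]
    n, d, h, wd, cin = x.data.shape
    cout = w.data.shape[-1]
    if k == 1:
        xmat = x.data.reshape(-1, cin)
        wmat = w.data.reshape(cin, cout)
        out = (xmat @ wmat + b.data).reshape(n, d, h, wd, cout)

        def backward1(g):
            gmat = g.reshape(-1, cout)
            w.accumulate((xmat.T @ gmat).reshape(w.data.shape))
            b.accumulate(gmat.sum(axis=0))
            x.accumulate((gmat @ wmat.T).reshape(x.data.shape))

        return Tensor(out, (x, w, b), backward1)

    # offset-sum formulation: one small GEMM per kernel offset over plain
    # block copies (much cheaper than gathering an im2col matrix)
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    vox = n * d * h * wd
    out_mat = np.tile(np.asarray(b.data, dtype=x.data.dtype), (vox, 1))
    offsets = [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]

    def shifted(arr, dz, dy, dx):
        return arr[:, dz:dz + d, dy:dy + h, dx:dx + wd, :].reshape(vox, -1)

    for dz, dy, dx in offsets:
        out_mat += shifted(xp, dz, dy, dx) @ w.data[dz, dy, dx]
    out = out_mat.reshape(n, d, h, wd, cout)

    def backward(g):
        gmat = np.ascontiguousarray(g).reshape(vox, cout)
        b.accumulate(gmat.sum(axis=0))
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for dz, dy, dx in offsets:
            v = shifted(xp, dz, dy, dx)
            dw[dz, dy, dx] = v.T @ gmat
            dxp[:, dz:dz + d, dy:dy + h, dx:dx + wd, :] += (
                gmat @ w.data[dz, dy, dx].T
            ).reshape(n, d, h, wd, cin)
        w.accumulate(dw)
        x.accumulate(dxp[:, pad:pad + d, pad:pad + h, pad:pad + wd, :])

    return Tensor(out, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling (spatial dims must be even)."""
    n, d, h, w, c = x.data.shape
    r = x.data.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4, 6))

    def backward(g):
        expanded = out[:, :, None, :, None, :, None, :]
        mask = r == expanded
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        gg = g[:, :, None, :, None, :, None, :] / cnt
        dx = (mask * gg).reshape(x.data.shape)
        x.accumulate(dx)

    return Tensor(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling of the three spatial dims."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, d, h, w, c = x.data.shape
        gr = g.reshape(n, d, 2, h, 2, w, 2, c).sum(axis=(2, 4, 6))
        x.accumulate(gr)

    return Tensor(out, (x,), backward)


def channel_standardize(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance-norm-style standardization: zero mean / unit variance per
    (sample, channel) over the spatial dims (no learned affine here)."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    m = x.data.shape[1] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        x.accumulate(inv * (g - gm - y * gym))

    return Tensor(y, (x,), backward)


def softmax_lastdim(x: Tensor) -> Tensor:
    """Numerically stable softmax over the last (channel) axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=-1, keepdims=True)
        x.accumulate(out * (g - dot))

    return Tensor(out, (x,), backward)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
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
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
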