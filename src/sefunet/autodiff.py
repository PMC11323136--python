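"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitive set the segmentation network needs:
elementwise arithmetic, matmul, (grouped/strided) 2-D convolution,
separable bilinear interpolation, reductions, concatenation and the
activation functions.  Gradients propagate through a dynamically built
tape; ``Tensor.backward()`` runs a topological sweep.

All data is kept in float32.  A module-level ``no_grad`` context disables
tape construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable gradient-tape construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_saved_sink")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    if p.requires_grad:
                        stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._push(g, grads)
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    def _push(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        self._saved_sink = grads  # type: ignore[attr-defined]
        try:
            self._backward(g)  # type: ignore[misc]
        finally:
            del self._saved_sink  # type: ignore[attr-defined]

    def _accum(self, parent: "Tensor", g: np.ndarray) -> None:
        sink: dict[int, np.ndarray] = self._saved_sink  # type: ignore[attr-defined]
        if not parent.requires_grad:
            return
        key = id(parent)
        if key in sink:
            sink[key] = sink[key] + g
        else:
            sink[key] = g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g, a=self, b=other):
            out._accum(a, _unbroadcast(g, a.shape))
            out._accum(b, _unbroadcast(g, b.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            out._accum(a, -g)

        out = Tensor._make(-self.data, (self,), bw)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g, a=self, b=other):
            out._accum(a, _unbroadcast(g * b.data, a.shape))
            out._accum(b, _unbroadcast(g * a.data, b.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g, a=self, b=other):
            out._accum(a, _unbroadcast(g / b.data, a.shape))
            out._accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g, a=self, e=exponent):
            out._accum(a, g * e * a.data ** (e - 1.0))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g, a=self, b=other):
            out._accum(a, g @ b.data.T)
            out._accum(b, a.data.T @ g)

        out = Tensor._make(out_data, (self, other), bw)
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g, a=self):
            out._accum(a, g.reshape(a.shape))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = np.ascontiguousarray(self.data.transpose(axes))

        def bw(g, a=self, inv=inv):
            out._accum(a, g.transpose(inv))

        out = Tensor._make(out_data, (self,), bw)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.broadcast_to(g, a.shape)
            out._accum(a, np.ascontiguousarray(grad))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g, a=self, mask=mask):
            out._accum(a, g * mask)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, s=out_data):
            out._accum(a, g * s * (1.0 - s))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def gelu(self):
        # tanh approximation
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g, a=self, t=t, x=x, c=c):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
            out._accum(a, g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, e=out_data):
            out._accum(a, g * e)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def log(self):
        out_data = np.log(self.data)

        def bw(g, a=self):
            out._accum(a, g / a.data)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        out_data = np.maximum(self.data, lo)

        def bw(g, a=self, mask=mask):
            out._accum(a, g * mask)

        out = Tensor._make(out_data, (self,), bw)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# composite / structural operations
# ---------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, ts=tuple(tensors), axis=axis, splits=splits):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(ts, pieces):
            out._accum(t, np.ascontiguousarray(piece))

    out = Tensor._make(out_data, tensors, bw)
    return out


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(xpad: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> windows (N, C, Ho, Wo, k, k) view."""
    win = sliding_window_view(xpad, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    ``weight`` has shape (C_out, C_in // groups, k, k).  ``groups == C_in``
    with one output per group is a depthwise convolution.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n, cin, h, w = x.shape
    cout, cing, kh, kw = weight.shape
    if kh != kw:
        raise ValueError("only square kernels supported")
    if cin != cing * groups or cout % groups:
        raise ValueError(
            f"channel mismatch: input {cin}, weight {weight.shape}, groups {groups}")
    k = kh
    ho, wo = _out_size(h, k, stride, padding), _out_size(w, k, stride, padding)
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than padded input")
    if padding:
        xpad = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xpad = x.data
    win = _im2col(xpad, k, stride)  # (N, C, Ho, Wo, k, k)
    coutg = cout // groups
    wg = weight.data.reshape(groups, coutg, cing, k, k)
    # cols: (N, groups, Ho*Wo, cing*k*k)
    cols = win.reshape(n, groups, cing, ho, wo, k, k)
    cols = cols.transpose(0, 1, 3, 4, 2, 5, 6).reshape(n, groups, ho * wo, cing * k * k)
    wmat = wg.reshape(groups, coutg, cing * k * k)
    out_np = np.einsum("ngpk,gok->ngop", cols, wmat, optimize=True)
    out_np = out_np.reshape(n, cout, ho, wo)
    if bias is not None:
        out_np = out_np + bias.data.reshape(1, cout, 1, 1)

    def bw(g, x=x, weight=weight, bias=bias, cols=cols, wmat=wmat,
           stride=stride, padding=padding, groups=groups, k=k,
           shapes=(n, cin, h, w, cout, cing, coutg, ho, wo)):
        n, cin, h, w, cout, cing, coutg, ho, wo = shapes
        gg = g.reshape(n, groups, coutg, ho * wo)
        if weight.requires_grad:
            dwmat = np.einsum("ngop,ngpk->gok", gg, cols, optimize=True)
            out._accum(weight, dwmat.reshape(cout, cing, k, k))
        if bias is not None and bias.requires_grad:
            out._accum(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # transposed convolution: dilate grad by stride, full-pad, flip kernel
            if stride > 1:
                gd = np.zeros((n, cout, (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                              dtype=np.float32)
                gd[:, :, ::stride, ::stride] = g
            else:
                gd = g
            gp = np.pad(gd, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
            wflip = weight.data.reshape(groups, coutg, cing, k, k)[:, :, :, ::-1, ::-1]
            winb = _im2col(gp, k, 1)  # (N, Cout, Hd+k-1, Wd+k-1, k, k)
            hd, wd = winb.shape[2], winb.shape[3]
            colsb = winb.reshape(n, groups, coutg, hd, wd, k, k)
            colsb = colsb.transpose(0, 1, 3, 4, 2, 5, 6).reshape(
                n, groups, hd * wd, coutg * k * k)
            wmatb = np.ascontiguousarray(wflip.transpose(0, 2, 1, 3, 4)).reshape(
                groups, cing, coutg * k * k)
            dxp = np.einsum("ngpk,gck->ngcp", colsb, wmatb, optimize=True)
            dxp = dxp.reshape(n, cin, hd, wd)
            dxpad = np.zeros((n, cin, h + 2 * padding, w + 2 * padding), dtype=np.float32)
            dxpad[:, :, :hd, :wd] = dxp
            if padding:
                dxpad = dxpad[:, :, padding:-padding, padding:-padding]
            out._accum(x, np.ascontiguousarray(dxpad))

    out = Tensor._make(out_np, (x, weight) + (() if bias is None else (bias,)), bw)
    return out


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear resampling matrix (n_out, n_in), half-pixel centers
    (align_corners = False)."""
    key = (n_in, n_out)
    mat = _INTERP_CACHE.get(key)
    if mat is not None:
        return mat
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        mat[i, lo] += 1.0 - t
        mat[i, hi] += t
    _INTERP_CACHE[key] = mat
    return mat


def interpolate_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (align_corners=False)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ah = _interp_matrix(h, out_h)
    aw = _interp_matrix(w, out_w)
    tmp = np.einsum("oh,nchw->ncow", ah, x.data, optimize=True)
    out_np = np.einsum("pw,ncow->ncop", aw, tmp, optimize=True)

    def bw(g, x=x, ah=ah, aw=aw):
        tmpb = np.einsum("pw,ncop->ncow", aw, g, optimize=True)
        dx = np.einsum("oh,ncow->nchw", ah, tmpb, optimize=True)
        out._accum(x, dx)

    out = Tensor._make(out_np, (x,), bw)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = as_tensor(x)
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-3) -> np.ndarray:
    """Central finite-difference gradient, used by the test-suite only."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp.astype(np.float32)) - f(xm.astype(np.float32))) / (2 * eps)
        it.iternext()
    return g
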