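"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is deliberately small — exactly
what the generators, discriminators and loss functions of this package need:
broadcasting arithmetic, matmul, reductions, shape ops, the usual pointwise
nonlinearities, and strided 2-D convolution / transposed convolution
implemented via im2col so the heavy lifting stays inside BLAS.

All tensors are float64 unless constructed otherwise.  The engine is
single-threaded and eager; there is no graph reuse, which keeps semantics
trivial (every forward pass builds a fresh graph).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "same_pads",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph machinery --------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar if grad omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(a.T @ g)
            else:  # batched: broadcast over leading dims
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accumulate(_unbroadcast(ga, a.shape))
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        out = Tensor(self.data * scale, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * scale)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * inside)
        return out

    # -- reductions & shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    """TF-style 'same' padding so that output size = ceil(size / stride)."""
    out = math.ceil(size / s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (N, C, Ho, Wo, kh, kw)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return cols, ho, wo


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: str | tuple[int, int, int, int] = "same",
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, weight (Cout, Cin, kh, kw).

    ``padding`` is either ``"same"`` (output = ceil(input/stride)),
    ``"valid"`` or an explicit ``(top, bottom, left, right)`` tuple.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s = stride
    if padding == "same":
        pt, pb = same_pads(h, kh, s)
        pl, pr = same_pads(wd, kw, s)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        pt, pb, pl, pr = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    cols, ho, wo = _im2col(xp, kh, kw, s, s)
    wm = w.data.reshape(cout, -1)
    y = cols @ wm.T  # (N, Ho*Wo, Cout)
    y = y.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    out = Tensor(y, _parents=parents)

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, cout)
        w._accumulate(
            (gm.reshape(-1, cout).T @ cols.reshape(-1, cin * kh * kw)).reshape(w.shape)
        )
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = gm @ wm  # (N, Ho*Wo, Cin*kh*kw)
        dcols = dcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += dcols[
                    :, :, :, :, i, j
                ]
        x._accumulate(dxp[:, :, pt : pt + h, pl : pl + wd])

    out._backward = bw
    return out


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
) -> Tensor:
    """Transposed convolution, NCHW, weight (Cin, Cout, kh, kw).

    Output spatial size is exactly ``input * stride`` (the 'same'-style
    up-sampling used throughout the generators; requires kernel >= stride).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {cin} vs {cin_w}")
    s = stride
    hout, wout = h * s, wd * s
    tot_h, tot_w = kh - s, kw - s
    if tot_h < 0 or tot_w < 0:
        raise ValueError("kernel must be >= stride")
    pt, pl = tot_h // 2, tot_w // 2
    hfull, wfull = (h - 1) * s + kh, (wd - 1) * s + kw

    wm = w.data.reshape(cin, cout * kh * kw)
    cols = x.data.transpose(0, 2, 3, 1).reshape(n, h * wd, cin) @ wm
    cols = cols.reshape(n, h, wd, cout, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    yfull = np.zeros((n, cout, hfull, wfull))
    for i in range(kh):
        for j in range(kw):
            yfull[:, :, i : i + s * (h - 1) + 1 : s, j : j + s * (wd - 1) + 1 : s] += cols[
                :, :, :, :, i, j
            ]
    y = yfull[:, :, pt : pt + hout, pl : pl + wout]
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y.copy(), _parents=parents)

    def bw(g):
        gfull = np.zeros((n, cout, hfull, wfull))
        gfull[:, :, pt : pt + hout, pl : pl + wout] = g
        dcols = np.empty((n, cout, h, wd, kh, kw))
        for i in range(kh):
            for j in range(kw):
                dcols[:, :, :, :, i, j] = gfull[
                    :, :, i : i + s * (h - 1) + 1 : s, j : j + s * (wd - 1) + 1 : s
                ]
        dcols_m = dcols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, cout * kh * kw)
        xm = x.data.transpose(0, 2, 3, 1).reshape(n, h * wd, cin)
        w._accumulate(
            (xm.reshape(-1, cin).T @ dcols_m.reshape(-1, cout * kh * kw)).reshape(w.shape)
        )
        x._accumulate(
            (dcols_m @ wm.T).reshape(n, h, wd, cin).transpose(0, 3, 1, 2)
        )
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out
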