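"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape: each :class:`Tensor` records its parents and a vector-Jacobian
closure; :meth:`Tensor.backward` walks the graph in reverse topological order
and accumulates gradients into leaf tensors.  Only the primitives needed by
the segmentation network are implemented (elementwise arithmetic, reductions,
2-D convolution / transpose convolution via im2col, max-pooling, softmax,
PReLU, dropout, concatenation and slicing).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "logcosh",
    "softmax",
    "prelu",
    "maxpool2d",
    "conv2d",
    "conv_transpose2d",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._vjps = vjps

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------------
    def _make(self, data, parents, vjps) -> "Tensor":
        live = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
        if not live:
            return Tensor(data)
        ps, vs = zip(*live)
        return Tensor(data, parents=ps, vjps=vs)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self.data + other.data
        return self._make(
            out,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self.data * other.data
        return self._make(
            out,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.shape),
                lambda g: _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return self._make(
            out,
            (self, other),
            (
                lambda g: _unbroadcast(g / other.data, self.shape),
                lambda g: _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data**exponent
        # guard the vjp at base -> 0 with fractional exponents (focal term)
        base = np.maximum(np.abs(self.data), 1e-12) * np.sign(self.data + 1e-300)

        def vjp(g):
            return g * exponent * base ** (exponent - 1)

        return self._make(out, (self,), (vjp,))

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, tuple) else (axis,))
            return np.broadcast_to(g, self.shape).copy()

        return self._make(out, (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = self.data.reshape(*shape)
        return self._make(out, (self,), (lambda g: g.reshape(self.shape),))

    def __getitem__(self, idx):
        out = self.data[idx]

        def vjp(g):
            full = np.zeros(self.shape)
            full[idx] = g
            return full

        return self._make(out, (self,), (vjp,))

    def log(self):
        return self._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), (lambda g: g * out,))

    # -- backward -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                pg = vjp(g)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg
            if node._parents:  # free intermediate grads, keep leaves
                node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / activation primitives
# ---------------------------------------------------------------------------


def _logcosh_np(x: np.ndarray) -> np.ndarray:
    # numerically stable log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def logcosh(x):
    """log(cosh(x)); accepts plain arrays/scalars or Tensors."""
    if not isinstance(x, Tensor):
        return _logcosh_np(np.asarray(x, dtype=np.float64))
    out = _logcosh_np(x.data)
    return x._make(out, (x,), (lambda g: g * np.tanh(x.data),))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return s * (g - dot)

    return x._make(s, (x,), (vjp,))


def prelu(x: Tensor, alpha: Tensor, channel_axis: int = 1) -> Tensor:
    """Parametric ReLU with one slope per channel."""
    shape = [1] * x.ndim
    shape[channel_axis] = alpha.data.size
    a = alpha.data.reshape(shape)
    pos = x.data > 0
    out = np.where(pos, x.data, a * x.data)

    def vjp_x(g):
        return np.where(pos, g, a * g)

    def vjp_a(g):
        axes = tuple(i for i in range(x.ndim) if i != channel_axis)
        return np.where(pos, 0.0, g * x.data).sum(axis=axes).reshape(alpha.shape)

    return x._make(out, (x, alpha), (vjp_x, vjp_a))


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep

    def vjp(g):
        return g * mask

    return x._make(x.data * mask, (x,), (vjp,))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    vjps = tuple(make_vjp(i) for i in range(len(tensors)))
    live = tensors[0]._make  # any instance works; use classmethod-like call
    return live(data, tuple(tensors), vjps)


# ---------------------------------------------------------------------------
# spatial primitives (NCHW layout)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (N, C*kh*kw, out_h*out_w)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    out_h = (hp - kh) // stride + 1
    out_w = (wp - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # N,C,out_h,out_w,kh,kw
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add columns back to image space (adjoint of :func:`_im2col`)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out_h = (hp - kh) // stride + 1
    out_w = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, out_h, out_w)
    img = np.zeros((n, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            img[:, :, i : i + stride * out_h : stride, j : j + stride * out_w : stride] += cols[
                :, :, i, j
            ]
    if pad:
        img = img[:, :, pad:-pad, pad:-pad]
    return img


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution. x: (N,C,H,W); weight: (Cout,Cin,kh,kw); bias: (Cout,)."""
    n, c, h, w = x.shape
    cout, cin, kh, kw = weight.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
    cols, out_h, out_w = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols).reshape(n, cout, out_h, out_w)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    def vjp_x(g):
        gmat = g.reshape(n, cout, out_h * out_w)
        dcols = np.matmul(wmat.T, gmat)
        return _col2im(dcols, x.shape, kh, kw, stride, pad)

    def vjp_w(g):
        gmat = g.reshape(n, cout, out_h * out_w)
        dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
        return dw.reshape(weight.shape)

    parents = [x, weight]
    vjps = [vjp_x, vjp_w]
    if bias is not None:
        parents.append(bias)
        vjps.append(lambda g: g.sum(axis=(0, 2, 3)))
    return x._make(out, tuple(parents), tuple(vjps))


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0
) -> Tensor:
    """Transpose convolution. weight: (Cin,Cout,kh,kw); output side = (H-1)*s + k - 2p."""
    n, c, h, w = x.shape
    cin, cout, kh, kw = weight.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
    out_h = (h - 1) * stride + kh - 2 * pad
    out_w = (w - 1) * stride + kw - 2 * pad
    wmat = weight.data.reshape(cin, cout * kh * kw)
    xmat = x.data.reshape(n, cin, h * w)
    cols = np.matmul(wmat.T, xmat)
    out = _col2im(cols, (n, cout, out_h, out_w), kh, kw, stride, pad)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    def vjp_x(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)
        return np.matmul(wmat, gcols).reshape(x.shape)

    def vjp_w(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)
        dw = np.matmul(xmat, gcols.transpose(0, 2, 1)).sum(axis=0)
        return dw.reshape(weight.shape)

    parents = [x, weight]
    vjps = [vjp_x, vjp_w]
    if bias is not None:
        parents.append(bias)
        vjps.append(lambda g: g.sum(axis=(0, 2, 3)))
    return x._make(out, tuple(parents), tuple(vjps))


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims ({h}x{w}) not divisible by pool size {size}")
    oh, ow = h // size, w // size
    xr = x.data.reshape(n, c, oh, size, ow, size).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, oh, ow, size * size)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        flat = np.zeros((n, c, oh, ow, size * size))
        np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
        flat = flat.reshape(n, c, oh, ow, size, size).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(x.shape)

    return x._make(out, (x,), (vjp,))
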