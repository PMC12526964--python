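"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives the dual-head conditional GAN
needs: elementwise arithmetic, activations, softplus (for overflow-safe
binary cross-entropy in logit space), channel concatenation, strided 2-D
convolution and transposed convolution (im2col based), batch
normalization, and dropout.  Gradients are accumulated by a topological
backward sweep, micrograd-style.

Arrays preserve the dtype they are given; training code uses float32,
gradient-check tests use float64.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, s: float):
        return self * (1.0 / float(s))

    def abs(self):
        sign = np.sign(self.data)
        out = _node(np.abs(self.data), (self,))
        out._backward = lambda g: self._accum(g * sign)
        return out

    def mean(self):
        out = _node(np.asarray(self.data.mean(), dtype=self.dtype), (self,))
        inv = 1.0 / self.data.size

        def bwd(g):
            self._accum(np.full_like(self.data, float(g) * inv))

        out._backward = bwd
        return out

    def sum(self):
        out = _node(np.asarray(self.data.sum(), dtype=self.dtype), (self,))
        out._backward = lambda g: self._accum(np.full_like(self.data, float(g)))
        return out

    # -- activations ---------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = _sigmoid(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope).astype(self.dtype)
        out = _node(self.data * scale, (self,))
        out._backward = lambda g: self._accum(g * scale)
        return out

    def softplus(self):
        """log(1 + e^x), computed overflow-safely; derivative is sigmoid."""
        x = self.data
        y = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * _sigmoid(x))
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(g, shape):
    """Reduce gradient g back to `shape` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            t._accum(p)

    out._backward = bwd
    return out


# -- convolution primitives -------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, OH*OW, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]          # (N,C,OH,OW,kh,kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add (N, OH*OW, C*kh*kw) patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return out[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation; w has shape (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: expected {cin} input channels, got {x.shape[1]}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wm = w.data.reshape(cout, -1)
    y = cols @ wm.T                                 # (N, OH*OW, Cout)
    if b is not None:
        y = y + b.data
    y = y.transpose(0, 2, 1).reshape(x.shape[0], cout, oh, ow)
    out = _node(y, (x, w) if b is None else (x, w, b))

    def bwd(g):
        gc = g.reshape(x.shape[0], cout, oh * ow).transpose(0, 2, 1)  # (N,P,Cout)
        if b is not None and (b.requires_grad or b._parents):
            b._accum(gc.sum(axis=(0, 1)))
        if w.requires_grad or w._parents:
            gw = gc.reshape(-1, cout).T @ cols.reshape(-1, cols.shape[2])
            w._accum(gw.reshape(w.shape))
        if x.requires_grad or x._parents:
            x._accum(_col2im(gc @ wm, x.shape, kh, kw, stride, pad))

    out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Transposed convolution; w has shape (Cin, Cout, kh, kw).

    Output spatial size is (H-1)*stride - 2*pad + k, the adjoint of the
    matching conv2d.
    """
    cin, cout, kh, kw = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv_transpose2d: expected {cin} input channels, got {x.shape[1]}")
    n, _, h, wdt = x.shape
    ho = (h - 1) * stride - 2 * pad + kh
    wo = (wdt - 1) * stride - 2 * pad + kw
    wm = w.data.reshape(cin, -1)                    # (Cin, Cout*kh*kw)
    xf = x.data.reshape(n, cin, h * wdt).transpose(0, 2, 1)  # (N,P,Cin)
    cols = xf @ wm                                  # (N,P,Cout*kh*kw)
    y = _col2im(cols, (n, cout, ho, wo), kh, kw, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]
    out = _node(y, (x, w) if b is None else (x, w, b))

    def bwd(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)      # (N,P,Cout*kh*kw)
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad or w._parents:
            gw = xf.reshape(-1, cin).T @ gcols.reshape(-1, gcols.shape[2])
            w._accum(gw.reshape(w.shape))
        if x.requires_grad or x._parents:
            gx = (gcols @ wm.T).transpose(0, 2, 1).reshape(x.shape)
            x._accum(gx)

    out._backward = bwd
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N,H,W); updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _node(y, (x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                dx = (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None]
            else:
                dx = dxhat / std[None, :, None, None]
            x._accum(dx)

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, active: bool) -> Tensor:
    """Inverted dropout; identity when inactive or p == 0."""
    if not active or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    out = _node(x.data * mask, (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out
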