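"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the detector needs: broadcast
elementwise arithmetic, exp/log/sqrt/clamp, sigmoid-family activations,
grouped 2-D convolution via im2col, stride-1 max pooling, batch
normalization, nearest-neighbour upsampling, concatenation, reductions
and fancy indexing.  Gradients flow through a topologically sorted tape,
torch-style: ``loss.backward()`` populates ``.grad`` on every leaf with
``requires_grad=True``.

All floating point work is float32; shapes follow the (N, C, H, W)
convention of convolutional detectors.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else _as_array(grad).reshape(self.data.shape)
        )
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise binary ---------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def maximum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.maximum(a.data, b.data)

    def bw(g):
        mask = (a.data >= b.data).astype(DTYPE)
        a._accumulate(_unbroadcast(g * mask, a.data.shape))
        b._accumulate(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(data, (a, b), bw)


def minimum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.minimum(a.data, b.data)

    def bw(g):
        mask = (a.data <= b.data).astype(DTYPE)
        a._accumulate(_unbroadcast(g * mask, a.data.shape))
        b._accumulate(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(data, (a, b), bw)


# -- elementwise unary ----------------------------------------------------

def power(a, p: float):
    a = _wrap(a)
    data = a.data ** p

    def bw(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), bw)


def exp(a):
    a = _wrap(a)
    data = np.exp(a.data)

    def bw(g):
        a._accumulate(g * data)

    return _make(data, (a,), bw)


def log(a):
    a = _wrap(a)
    data = np.log(a.data)

    def bw(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), bw)


def sqrt(a):
    a = _wrap(a)
    data = np.sqrt(a.data)

    def bw(g):
        a._accumulate(g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), bw)


def absolute(a):
    a = _wrap(a)
    data = np.abs(a.data)

    def bw(g):
        a._accumulate(g * np.sign(a.data))

    return _make(data, (a,), bw)


def clamp(a, lo=None, hi=None):
    a = _wrap(a)
    data = np.clip(a.data, lo, hi)

    def bw(g):
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= (a.data >= lo)
        if hi is not None:
            mask *= (a.data <= hi)
        a._accumulate(g * mask)

    return _make(data, (a,), bw)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    z = np.exp(-np.abs(x))
    z1 = 1.0 + z
    return np.where(x >= 0, 1.0 / z1, z / z1)


def sigmoid(a):
    a = _wrap(a)
    data = _stable_sigmoid(a.data)

    def bw(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), bw)


def silu(a):
    """x * sigmoid(x) — the smooth gated activation of detector conv blocks."""
    a = _wrap(a)
    s = _stable_sigmoid(a.data)
    data = a.data * s

    def bw(g):
        a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(data, (a,), bw)


def hardswish(a):
    a = _wrap(a)
    r = np.clip(a.data + 3.0, 0.0, 6.0)
    data = a.data * r / 6.0

    def bw(g):
        inner = np.where((a.data > -3.0) & (a.data < 3.0), a.data / 6.0, 0.0)
        a._accumulate(g * (r / 6.0 + inner))

    return _make(data, (a,), bw)


# -- shape ops ------------------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    data = a.data.reshape(shape)
    old = a.data.shape

    def bw(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), bw)


def transpose(a, axes):
    a = _wrap(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), bw)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), bw)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice, type(Ellipsis), type(None))) for i in items)


def getitem(a, idx):
    a = _wrap(a)
    data = a.data[idx]
    basic = _is_basic_index(idx)

    def bw(g):
        full = np.zeros_like(a.data)
        if basic:
            full[idx] += g
        else:
            np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(data, (a,), bw)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(DTYPE))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(DTYPE))

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def stack(tensors, axis=0):
    expanded = [reshape(t, t.data.shape[:axis] + (1,) + t.data.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)


# -- convolution ----------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, s: int):
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, s: int):
    n, c, hp, wp = xp_shape
    ho, wo = dcols.shape[-2:]
    dxp = np.zeros(xp_shape, dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
    return dxp


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """Grouped 2-D convolution; w has shape (c_out, c_in/groups, kh, kw)."""
    x, w = _wrap(x), _wrap(w)
    n, c_in, h, wd = x.data.shape
    c_out, cpg, kh, kw = w.data.shape
    assert c_in == cpg * groups, "channel/group mismatch"
    g_ = groups
    opg = c_out // g_
    k_flat = cpg * kh * kw
    pointwise = kh == 1 and kw == 1 and stride == 1 and padding == 0
    if pointwise:
        xp_shape = None
        ho, wo = h, wd
        colsm = x.data.reshape(n, g_, k_flat, ho * wo)
    else:
        xp = (
            np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
            if padding
            else x.data
        )
        xp_shape = xp.shape
        cols, ho, wo = _im2col(xp, kh, kw, stride)
        colsm = np.ascontiguousarray(cols.reshape(n, c_in, kh * kw, ho * wo)
                                     .reshape(n, g_, k_flat, ho * wo))
    wm = w.data.reshape(g_, opg, k_flat)
    # batched BLAS matmul: (g, opg, K) @ (n, g, K, L) -> (n, g, opg, L)
    out = np.matmul(wm, colsm).reshape(n, c_out, ho, wo)
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out += b.data.reshape(1, c_out, 1, 1)
        parents.append(b)

    def bw(g):
        gm = g.reshape(n, g_, opg, ho * wo)
        dw = np.matmul(gm, colsm.swapaxes(-1, -2)).sum(axis=0)
        w._accumulate(dw.reshape(w.data.shape))
        dcols = np.matmul(wm.swapaxes(-1, -2), gm)
        if pointwise:
            x._accumulate(dcols.reshape(n, c_in, h, wd))
        else:
            dcols = dcols.reshape(n, c_in, kh, kw, ho, wo)
            dxp = _col2im(dcols, xp_shape, kh, kw, stride)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, tuple(parents), bw)


def max_pool2d(x, k: int, stride: int = 1, padding: int = 0):
    """Max pooling; stride-1 padded form preserves spatial dims (SPPF)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    cols, ho, wo = _im2col(xp, k, k, stride)
    out = cols.max(axis=(2, 3))

    def bw(g):
        mask = cols == out[:, :, None, None, :, :]
        mask = mask / np.maximum(mask.sum(axis=(2, 3), keepdims=True), 1)
        dcols = mask.astype(DTYPE) * g[:, :, None, None, :, :]
        dxp = _col2im(dcols, xp.shape, k, k, stride)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return _make(out, (x,), bw)


def upsample_nearest2x(x):
    x = _wrap(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(data, (x,), bw)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.03, eps: float = 1e-3, update_stats=None,
               second_moment: bool = False):
    """Channel batch normalization over (N, H, W); running stats updated
    in-place.  `update_stats` decouples statistic recording from the
    normalization mode (used for post-hoc calibration); it defaults to
    `training`."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    if update_stats is None:
        update_stats = training
    if update_stats:
        mu_b = x.data.mean(axis=axes)
        var_b = x.data.var(axis=axes)
        m = x.data.size / c
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu_b
        running_var *= 1.0 - momentum
        if second_moment:
            # accumulate E[x^2] so across-batch mean variation is captured;
            # the caller converts back to a variance afterwards
            running_var += momentum * (var_b + mu_b**2)
        else:
            running_var += momentum * var_b * (m / max(m - 1.0, 1.0))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    else:
        mu, var = running_mean.copy(), running_var.copy()
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gi = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = x.data.size / c
            t1 = gi.sum(axis=axes, keepdims=True) / m
            t2 = (gi * xhat).sum(axis=axes, keepdims=True) / m
            dx = (gi - t1 - xhat * t2) * inv.reshape(1, c, 1, 1)
        else:
            dx = gi * inv.reshape(1, c, 1, 1)
        x._accumulate(dx.astype(DTYPE))

    return _make(out, (x, gamma, beta), bw)


# -- optimizer ------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
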