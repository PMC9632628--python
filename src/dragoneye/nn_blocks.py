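"""Building blocks of the lightweight fruit-detection network.

Every block is a :class:`Module` whose trainable parameter count has a
closed form (``closed_form_params``) verifiable against brute-force
enumeration of its weight tensors (``param_count``).  Conventions that
the per-layer parameter table pins down exactly:

* convolutions inside Conv/Ghost blocks are bias-free and followed by
  batch normalization (2 trainable parameters per channel: scale and
  shift; running statistics are not trainable);
* ghost convolutions split the output width in half: a primary k x k
  convolution produces the intrinsic maps and a depthwise 5 x 5 "cheap
  operation" produces the ghost maps, concatenated channel-wise;
* coordinate attention uses hidden width m = max(16, c // 16), a biased
  first 1 x 1 convolution followed by batch norm and hard-swish, and two
  bias-free gate convolutions each followed by batch norm and a sigmoid;
* the weighted bidirectional fusion layer owns one learnable scalar per
  input, normalized by max(w, 0) / (sum max(w, 0) + eps).
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "Conv", "GhostConv", "GhostBottleneck", "C3Ghost", "Bottleneck",
    "C3", "SPPF", "CoordAttention", "BiFPNConcat", "Upsample", "Detect",
    "conv_bn_act", "ghost_conv", "ghost_bottleneck", "c3ghost", "c3", "sppf",
    "coord_attention", "bifpn_concat", "detect_head", "ghost_speedup_ratio",
    "ghost_compression_ratio",
]


class Module:
    """Base class: tracks sub-modules and parameters, torch-style."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self):
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix=""):
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def buffers(self):
        for m in self._modules.values():
            yield from m.buffers()

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        """Brute-force enumeration of weight-tensor element counts."""
        return int(sum(p.size for p in self.parameters()))

    def closed_form_params(self) -> int:
        raise NotImplementedError

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_dict(self):
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        for i, b in enumerate(self.buffers()):
            d[f"__buffer_{i}"] = b.copy()
        return d

    def load_state_dict(self, d):
        for k, p in self.named_parameters():
            p.data[...] = d[k]
        for i, b in enumerate(self.buffers()):
            b[...] = d[f"__buffer_{i}"]


def _kaiming(shape, fan_in, rng):
    bound = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, bound, size=shape), requires_grad=True)


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int):
    """Reseed weight initialization (all randomness flows from one master seed)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.weight = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)
        object.__setattr__(self, "running_mean", np.zeros(c, dtype=ag.DTYPE))
        object.__setattr__(self, "running_var", np.ones(c, dtype=ag.DTYPE))
        self.eps = eps
        self.momentum = momentum
        self.calibrating = False

    def buffers(self):
        yield self.running_mean
        yield self.running_var

    def forward(self, x):
        return ag.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
            update_stats=True if self.calibrating else None,
            second_moment=self.calibrating,
        )


_ACTS = {"silu": ag.silu, "hardswish": ag.hardswish, "sigmoid": ag.sigmoid, None: lambda t: t}


class Conv(Module):
    """Bias-free convolution + batch norm + activation (default: SiLU).

    Trainable parameters: ``c1*c2*k*k/g + 2*c2``.
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="silu"):
        super().__init__()
        if c1 <= 0 or c2 <= 0:
            raise ValueError(f"channel counts must be positive, got {c1}->{c2}")
        if p is None:
            p = k // 2
        self.weight = _kaiming((c2, c1 // g, k, k), c1 // g * k * k, _INIT_RNG)
        self.bn = BatchNorm2d(c2)
        self.c1, self.c2, self.k, self.s, self.p, self.g = c1, c2, k, s, p, g
        self.act = act

    def forward(self, x):
        y = ag.conv2d(x, self.weight, stride=self.s, padding=self.p, groups=self.g)
        return _ACTS[self.act](self.bn(y))

    def closed_form_params(self):
        return self.c1 * self.c2 * self.k ** 2 // self.g + 2 * self.c2

    def out_spatial(self, h, w):
        return (
            (h + 2 * self.p - self.k) // self.s + 1,
            (w + 2 * self.p - self.k) // self.s + 1,
        )


class GhostConv(Module):
    """Ghost convolution: primary conv to c2/2 intrinsic maps, depthwise
    5x5 cheap operation for the other c2/2 ghost maps, concatenated.

    Intrinsic ratio s = 2 (half/half split), the setting that reproduces
    every printed per-layer count of the reference architecture.
    """

    def __init__(self, c1, c2, k=1, s=1, act="silu"):
        super().__init__()
        if c2 % 2:
            raise ValueError("ghost convolution needs an even output width")
        c_ = c2 // 2
        self.cv1 = Conv(c1, c_, k, s, act=act)
        self.cv2 = Conv(c_, c_, 5, 1, p=2, g=c_, act=act)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s

    def forward(self, x):
        y = self.cv1(x)
        return ag.concat([y, self.cv2(y)], axis=1)

    def closed_form_params(self):
        c_ = self.c2 // 2
        return self.c1 * c_ * self.k ** 2 + 2 * c_ + c_ * 25 + 2 * c_


class GhostBottleneck(Module):
    """Stride-1 ghost bottleneck: two 1x1 ghost convolutions (second one
    linear) around an identity shortcut.  The stride-2 depthwise variant
    is not used anywhere in this architecture and is rejected."""

    def __init__(self, c1, c2, k=1, s=1):
        super().__init__()
        if s != 1:
            raise NotImplementedError("stride-2 ghost bottleneck not supported")
        if c1 % 2 or c2 % 2:
            raise ValueError("channel widths must be even")
        c_ = c2 // 2
        self.cv1 = GhostConv(c1, c_, 1, 1)
        self.cv2 = GhostConv(c_, c2, 1, 1, act=None)
        self.add = c1 == c2
        self.c1, self.c2 = c1, c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def closed_form_params(self):
        return self.cv1.closed_form_params() + self.cv2.closed_form_params()


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_, c2, 3, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def closed_form_params(self):
        return self.cv1.closed_form_params() + self.cv2.closed_form_params()


class _CSP(Module):
    """Cross-stage partial scaffold: two 1x1 branches, n inner blocks on
    one of them, concat, 1x1 re-projection."""

    def __init__(self, c1, c2, n, inner):
        super().__init__()
        if n < 1:
            raise ValueError("repeat count must be >= 1")
        c_ = c2 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1, 1)
        self.m = [inner(c_) for _ in range(n)]
        self.c1, self.c2 = c1, c2

    def forward(self, x):
        y = self.cv1(x)
        for blk in self.m:
            y = blk(y)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))

    def closed_form_params(self):
        return (
            self.cv1.closed_form_params()
            + self.cv2.closed_form_params()
            + self.cv3.closed_form_params()
            + sum(b.closed_form_params() for b in self.m)
        )


class C3(_CSP):
    def __init__(self, c1, c2, n=1, shortcut=True):
        super().__init__(c1, c2, n, lambda c_: Bottleneck(c_, c_, shortcut, e=1.0))


class C3Ghost(_CSP):
    def __init__(self, c1, c2, n=1):
        super().__init__(c1, c2, n, lambda c_: GhostBottleneck(c_, c_))


class SPPF(Module):
    """Fast spatial pyramid pooling: 1x1 reduce to c1/2, three chained
    stride-1 max pools (kernel k, padding k//2), concat of the four maps,
    1x1 projection to c2.  Spatial dimensions are preserved."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("pool kernel must be odd")
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)
        self.k = k
        self.c1, self.c2 = c1, c2

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = ag.max_pool2d(y0, self.k, 1, self.k // 2)
        y2 = ag.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = ag.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(ag.concat([y0, y1, y2, y3], axis=1))

    def closed_form_params(self):
        return self.cv1.closed_form_params() + self.cv2.closed_form_params()


class CoordAttention(Module):
    """Coordinate attention: features pooled into per-axis 1-D descriptors,
    jointly encoded, then re-expanded into sigmoid gates for each axis.

    Output shape equals input shape; with both gates forced to one the
    block is the identity.
    """

    def __init__(self, c, c_out=None):
        super().__init__()
        if c < 1:
            raise ValueError("channel count must be positive")
        if c_out is not None and c_out != c:
            raise ValueError("coordinate attention preserves channel width")
        m = max(16, c // 16)
        self.conv1 = Conv(c, m, 1, 1, act=None)  # replaced weight below: biased variant
        # first transform: biased 1x1 conv + BN + hard-swish
        self.conv1_bias = Tensor(np.zeros(m), requires_grad=True)
        self.conv_h = Conv(m, c, 1, 1, act=None)
        self.conv_w = Conv(m, c, 1, 1, act=None)
        self.c, self.m = c, m

    def forward(self, x):
        n, c, h, w = x.shape
        xh = ag.tmean(x, axis=3, keepdims=True)                       # (n,c,h,1)
        xw = ag.transpose(ag.tmean(x, axis=2, keepdims=True), (0, 1, 3, 2))  # (n,c,w,1)
        y = ag.concat([xh, xw], axis=2)                               # (n,c,h+w,1)
        y = ag.conv2d(y, self.conv1.weight, self.conv1_bias)
        y = ag.hardswish(self.conv1.bn(y))
        gh = ag.sigmoid(self.conv_h.bn(ag.conv2d(y[:, :, :h], self.conv_h.weight)))
        gw = ag.sigmoid(self.conv_w.bn(ag.conv2d(y[:, :, h:], self.conv_w.weight)))
        gw = ag.transpose(gw, (0, 1, 3, 2))                           # (n,c,1,w)
        return x * gh * gw

    def closed_form_params(self):
        c, m = self.c, self.m
        return 3 * c * m + 3 * m + 4 * c


class BiFPNConcat(Module):
    """Weighted channel-wise concatenation with fast normalized fusion:
    each input is scaled by max(w_i, 0) / (sum_j max(w_j, 0) + eps)
    before concatenation.  One learnable scalar per input, initialized
    to 1; eps = 1e-4."""

    EPS = 1e-4

    def __init__(self, n_inputs=2):
        super().__init__()
        if n_inputs < 1:
            raise ValueError("fusion needs at least one input")
        self.w = Tensor(np.ones(n_inputs), requires_grad=True)
        self.n_inputs = n_inputs

    def normalized_weights(self):
        w = np.maximum(self.w.data, 0.0)
        return w / (w.sum() + self.EPS)

    def forward(self, xs):
        if len(xs) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {len(xs)}")
        hw = {tuple(x.shape[2:]) for x in xs}
        if len(hw) != 1:
            raise ValueError(f"spatial dims of fused inputs differ: {sorted(hw)}")
        w = ag.clamp(self.w, lo=0.0)
        denom = ag.tsum(w) + self.EPS
        scaled = [xs[i] * (w[i] / denom) for i in range(self.n_inputs)]
        return ag.concat(scaled, axis=1)

    def closed_form_params(self):
        return self.n_inputs


class Upsample(Module):
    """Nearest-neighbour x2 upsampling; parameter-free."""

    def __init__(self):
        super().__init__()

    def forward(self, x):
        return ag.upsample_nearest2x(x)

    def closed_form_params(self):
        return 0


class Detect(Module):
    """Anchor-based prediction head: per scale a biased 1x1 convolution to
    n_anchors * (n_classes + 5) channels (box, objectness, class scores)."""

    def __init__(self, ch, nc=1, anchors=None, no_override=None):
        super().__init__()
        if nc < 1:
            raise ValueError("need at least one class")
        if anchors is None:
            # three per scale, scaled for 640-pixel input (strides 8/16/32)
            anchors = [
                [(10, 13), (16, 30), (33, 23)],
                [(30, 61), (62, 45), (59, 119)],
                [(116, 90), (156, 198), (373, 326)],
            ]
        self.nc = nc
        self.na = len(anchors[0])
        self.no = no_override if no_override is not None else self.na * (nc + 5)
        if len(anchors) != len(ch):
            raise ValueError("one anchor set per input scale required")
        object.__setattr__(self, "anchors", np.asarray(anchors, dtype=ag.DTYPE))
        self.ch = tuple(ch)
        self.m = [self._head_conv(c) for c in ch]

    def _head_conv(self, c):
        mod = Module()
        mod.weight = _kaiming((self.no, c, 1, 1), c, _INIT_RNG)
        mod.bias = Tensor(np.zeros(self.no), requires_grad=True)
        mod.forward = lambda x, w=mod.weight, b=mod.bias: ag.conv2d(x, w, b)
        mod.closed_form_params = lambda: (c + 1) * self.no
        return mod

    def init_biases(self, strides, img_size=640.0):
        """Objectness prior: start rare-positive so early training is stable."""
        if self.no != self.na * (self.nc + 5):
            return
        for conv, s in zip(self.m, strides):
            b = conv.bias.data.reshape(self.na, self.nc + 5)
            b[:, 4] += math.log(8.0 / (img_size / s) ** 2)
            if self.nc > 0:
                b[:, 5:] += math.log(0.6 / (self.nc - 0.999999)) if self.nc > 1 else math.log(0.6 / 0.01)

    def forward(self, xs):
        if len(xs) != len(self.m):
            raise ValueError(f"expected {len(self.m)} feature maps, got {len(xs)}")
        return [conv(x) for conv, x in zip(self.m, xs)]

    def closed_form_params(self):
        return sum((c + 1) * self.no for c in self.ch)


# -- spec-level factory functions ----------------------------------------

def conv_bn_act(c_in, c_out, k, s, p=None):
    return Conv(c_in, c_out, k, s, p)


def ghost_conv(c_in, c_out, k=1, s=1):
    return GhostConv(c_in, c_out, k, s)


def ghost_bottleneck(c_in, c_out, s=1):
    return GhostBottleneck(c_in, c_out, s=s)


def c3ghost(c_in, c_out, n=1):
    return C3Ghost(c_in, c_out, n)


def c3(c_in, c_out, n=1, shortcut=True):
    return C3(c_in, c_out, n, shortcut)


def sppf(c_in, c_out, k=5):
    return SPPF(c_in, c_out, k)


def coord_attention(c):
    return CoordAttention(c)


def bifpn_concat(n_inputs=2):
    return BiFPNConcat(n_inputs)


def detect_head(in_channels, n_anchors=3, n_classes=1, no_override=None):
    anchors = [[(10.0 * 2 ** i, 10.0 * 2 ** i)] * n_anchors for i in range(len(in_channels))]
    return Detect(list(in_channels), nc=n_classes, anchors=anchors, no_override=no_override)


# -- ghost speed-up / compression ratios ---------------------------------

def ghost_speedup_ratio(c, n, k, s=2, d=5, h_out=1, w_out=1):
    """Acceleration of a ghost module over a plain convolution of equal
    output width: r_s = n*h'*w'*c*k^2 / (n/s*h'*w'*c*k^2 + (s-1)*(n/s)*h'*w'*d^2)."""
    plain = n * h_out * w_out * c * k * k
    ghost = (n / s) * h_out * w_out * c * k * k + (s - 1) * (n / s) * h_out * w_out * d * d
    return plain / ghost


def ghost_compression_ratio(c, n, k, s=2, d=5):
    """Parameter compression r_c = n*c*k^2 / (n/s*c*k^2 + (s-1)*(n/s)*d^2)."""
    plain = n * c * k * k
    ghost = (n / s) * c * k * k + (s - 1) * (n / s) * d * d
    return plain / ghost
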