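"""SIoU bounding-box regression loss: IoU, angle, distance and shape costs.

Boxes are center-size ``(cx, cy, w, h)``; pixels or normalized units are
both fine as long as a call is internally consistent (the loss is
translation- and scale-invariant).

The angle cost is

    Lambda = cos(2 * (arcsin(c_h / sigma) - pi/4))

where ``sigma`` is the center distance and ``c_h`` the absolute vertical
center gap.  Algebraically this equals ``2 * x * sqrt(1 - x^2)`` with
``x = c_h / sigma`` (i.e. ``sin(2 * alpha)``), the form used here: it is
zero when the centers are horizontally (alpha = 0) or vertically
(alpha = pi/2) aligned and maximal on the 45-degree diagonal, matching
the stated behaviour of the cost.  The total loss is

    L = 1 - IoU + (Delta + Omega) / 2

with distance cost ``Delta = 2 - exp(-gamma*rho_x) - exp(-gamma*rho_y)``
(``gamma = 2 - Lambda``, center offsets normalized by the enclosing-box
extents) and shape cost ``Omega`` summing ``(1 - exp(-|w - w_gt| /
max(w, w_gt)))**theta`` over both extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Box", "SIoUComponents", "iou", "angle_cost", "distance_cost",
    "shape_cost", "siou_loss", "siou_components", "siou_loss_tensor",
    "THETA_DEFAULT",
]

THETA_DEFAULT = 4.0  # shape-cost exponent, mid-range of the canonical [2, 6]


@dataclass
class Box:
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extents must be positive")

    @property
    def corners(self):
        return (
            self.cx - self.w / 2, self.cy - self.h / 2,
            self.cx + self.w / 2, self.cy + self.h / 2,
        )


@dataclass
class SIoUComponents:
    iou: float
    lambda_angle: float
    delta: float
    omega: float
    sigma: float
    ch: float
    cw1: float
    ch1: float
    theta: float

    @property
    def loss(self) -> float:
        return 1.0 - self.iou + (self.delta + self.omega) / 2.0


def _as_box(b) -> Box:
    if isinstance(b, Box):
        return b
    return Box(*b)


def iou(a, b) -> float:
    """Intersection over union; 0 for disjoint boxes."""
    a, b = _as_box(a), _as_box(b)
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def angle_cost(gt, pred) -> float:
    """Lambda in [0, 1]; 0 at horizontal or vertical center alignment."""
    gt, pred = _as_box(gt), _as_box(pred)
    dx = gt.cx - pred.cx
    dy = gt.cy - pred.cy
    sigma = float(np.hypot(dx, dy))
    if sigma == 0.0:
        return 0.0
    x = min(abs(dy) / sigma, 1.0)  # c_h / sigma, clamped against fp overshoot
    return float(2.0 * x * np.sqrt(max(1.0 - x * x, 0.0)))


def distance_cost(gt, pred, cw1: float, ch1: float, lambda_angle: float) -> float:
    """Delta = 2 - exp(-gamma*rho_x) - exp(-gamma*rho_y), gamma = 2 - Lambda."""
    if cw1 <= 0 or ch1 <= 0:
        raise ValueError("enclosing-box extents must be positive")
    gt, pred = _as_box(gt), _as_box(pred)
    gamma = 2.0 - lambda_angle
    rho_x = ((gt.cx - pred.cx) / cw1) ** 2
    rho_y = ((gt.cy - pred.cy) / ch1) ** 2
    return float(2.0 - np.exp(-gamma * rho_x) - np.exp(-gamma * rho_y))


def shape_cost(pred_wh, gt_wh, theta: float = THETA_DEFAULT) -> float:
    w, h = pred_wh
    wg, hg = gt_wh
    if min(w, h, wg, hg) <= 0:
        raise ValueError("extents must be positive")
    ww = (1.0 - np.exp(-abs(w - wg) / max(w, wg))) ** theta
    wh = (1.0 - np.exp(-abs(h - hg) / max(h, hg))) ** theta
    return float(ww + wh)


def _enclosing(a: Box, b: Box):
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    return max(ax2, bx2) - min(ax1, bx1), max(ay2, by2) - min(ay1, by1)


def siou_components(pred, gt, theta: float = THETA_DEFAULT) -> SIoUComponents:
    pred, gt = _as_box(pred), _as_box(gt)
    cw1, ch1 = _enclosing(pred, gt)
    lam = angle_cost(gt, pred)
    sigma = float(np.hypot(gt.cx - pred.cx, gt.cy - pred.cy))
    return SIoUComponents(
        iou=iou(pred, gt),
        lambda_angle=lam,
        delta=0.0 if sigma == 0.0 else distance_cost(gt, pred, cw1, ch1, lam),
        omega=shape_cost((pred.w, pred.h), (gt.w, gt.h), theta),
        sigma=sigma,
        ch=abs(gt.cy - pred.cy),
        cw1=cw1,
        ch1=ch1,
        theta=theta,
    )


def siou_loss(pred, gt, theta: float = THETA_DEFAULT) -> float:
    """1 - IoU + (Delta + Omega)/2; zero for identical boxes."""
    return siou_components(pred, gt, theta).loss


# -- batched autodiff form (the training path) ----------------------------

def siou_loss_tensor(pred: Tensor, gt: np.ndarray, theta: float = THETA_DEFAULT) -> Tensor:
    """Per-pair SIoU loss for a (M, 4) tensor of predicted center-size
    boxes against a (M, 4) array of targets; differentiable in `pred`.

    The c_h/sigma ratio is clamped just inside [0, 1] so the sqrt in the
    angle term keeps a finite gradient at exact vertical alignment.
    """
    gt = np.asarray(gt, dtype=ag.DTYPE)
    px, py = pred[:, 0], pred[:, 1]
    pw = ag.clamp(pred[:, 2], lo=1e-6)
    ph = ag.clamp(pred[:, 3], lo=1e-6)
    gx, gy, gw, gh = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]

    # IoU
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = gx - gw * 0.5, gx + gw * 0.5
    gy1, gy2 = gy - gh * 0.5, gy + gh * 0.5
    iw = ag.clamp(ag.minimum(px2, Tensor(gx2)) - ag.maximum(px1, Tensor(gx1)), lo=0.0)
    ih = ag.clamp(ag.minimum(py2, Tensor(gy2)) - ag.maximum(py1, Tensor(gy1)), lo=0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou_t = inter / (union + 1e-9)

    # enclosing box
    cw1 = ag.maximum(px2, Tensor(gx2)) - ag.minimum(px1, Tensor(gx1))
    ch1 = ag.maximum(py2, Tensor(gy2)) - ag.minimum(py1, Tensor(gy1))

    # angle cost: sin(2*alpha) = 2 x sqrt(1 - x^2), x = |dy| / sigma
    dx = Tensor(gx) - px
    dy = Tensor(gy) - py
    sigma = ag.sqrt(dx * dx + dy * dy + 1e-12)
    x = ag.clamp(ag.absolute(dy) / sigma, lo=0.0, hi=1.0 - 1e-6)
    lam = 2.0 * x * ag.sqrt(1.0 - x * x)

    # distance cost
    gamma = 2.0 - lam
    rho_x = (dx / (cw1 + 1e-9)) ** 2.0
    rho_y = (dy / (ch1 + 1e-9)) ** 2.0
    delta = 2.0 - ag.exp(-1.0 * gamma * rho_x) - ag.exp(-1.0 * gamma * rho_y)

    # shape cost
    ow = (1.0 - ag.exp(-1.0 * ag.absolute(pw - gw) / ag.maximum(pw, Tensor(gw)))) ** theta
    oh = (1.0 - ag.exp(-1.0 * ag.absolute(ph - gh) / ag.maximum(ph, Tensor(gh)))) ** theta
    omega = ow + oh

    return 1.0 - iou_t + (delta + omega) * 0.5
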