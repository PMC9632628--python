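"""Composite detection training loss with SIoU box regression.

Three terms, the curves a training log tracks:

* positioning — mean SIoU loss over matched anchor-target pairs;
* confidence — binary cross-entropy on objectness, with matched cells
  soft-labelled by the (detached) SIoU similarity, clipped to [0, 1];
* classification — binary cross-entropy on class scores; identically
  zero in the single-class setting.

Anchor matching is the standard shape-ratio scheme of the base detector
family: a target claims an anchor when max(wh/anchor, anchor/wh) < 4,
in its center cell plus the two adjacent cells nearest the center.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .siou import siou_loss_tensor

__all__ = ["build_targets", "detection_loss", "bce_with_logits", "LossWeights"]

ANCHOR_T = 4.0          # width/height ratio gate
OBJ_BALANCE = (4.0, 1.0, 0.4)   # per-scale objectness weights (P3, P4, P5)


class LossWeights:
    def __init__(self, box=0.05, obj=1.0, cls=0.5):
        self.box, self.obj, self.cls = box, obj, cls


def bce_with_logits(x: Tensor, z) -> Tensor:
    """Elementwise binary cross-entropy on logits, numerically stable:
    max(x,0) - x*z + log(1 + exp(-|x|))."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    return ag.clamp(x, lo=0.0) - x * z + ag.log(1.0 + ag.exp(-1.0 * ag.absolute(x)))


def build_targets(targets: np.ndarray, anchors: np.ndarray, strides, grids):
    """Assign normalized targets to (image, anchor, cell) slots per scale.

    targets: (T, 6) rows (img_idx, cls, cx, cy, w, h), coords normalized
    to the square input.  anchors: (n_scales, na, 2) in input pixels.
    grids: [(ny, nx), ...].  Returns per scale a dict with index arrays
    ``b, a, gj, gi``, target boxes in grid units (centers absolute) and
    the matched anchor extents in grid units.
    """
    out = []
    targets = np.asarray(targets, dtype=np.float32).reshape(-1, 6)
    for (ny, nx), stride, anc in zip(grids, strides, anchors):
        anc_g = anc / stride  # grid units
        if len(targets) == 0:
            out.append(None)
            continue
        t = targets.copy()
        t[:, 2] *= nx
        t[:, 4] *= nx
        t[:, 3] *= ny
        t[:, 5] *= ny
        na = len(anc_g)
        tt = np.repeat(t[None], na, axis=0)              # (na, T, 6)
        ai = np.repeat(np.arange(na)[:, None], t.shape[0], axis=1)
        r = tt[..., 4:6] / anc_g[:, None, :]
        keep = np.maximum(r, 1.0 / r).max(axis=2) < ANCHOR_T
        tt, ai = tt[keep], ai[keep]
        if len(tt) == 0:
            out.append(None)
            continue
        # center cell + the two nearest neighbours
        gxy = tt[:, 2:4]
        gxi = np.stack([nx - gxy[:, 0], ny - gxy[:, 1]], axis=1)
        g = 0.5
        jk = (gxy % 1.0 < g) & (gxy > 1.0)
        lm = (gxi % 1.0 < g) & (gxi > 1.0)
        sel = np.stack([np.ones(len(tt), bool), jk[:, 0], jk[:, 1], lm[:, 0], lm[:, 1]])
        offsets = np.array([[0, 0], [-g, 0], [0, -g], [g, 0], [0, g]], dtype=np.float32)
        tt5 = np.repeat(tt[None], 5, axis=0)[sel]
        ai5 = np.repeat(ai[None], 5, axis=0)[sel]
        off5 = np.repeat(offsets[:, None], len(tt), axis=1)[sel]
        gij = (tt5[:, 2:4] + off5).astype(int)
        gi = np.clip(gij[:, 0], 0, nx - 1)
        gj = np.clip(gij[:, 1], 0, ny - 1)
        out.append(
            {
                "b": tt5[:, 0].astype(int),
                "a": ai5,
                "gj": gj,
                "gi": gi,
                "tbox": np.concatenate([tt5[:, 2:4], tt5[:, 4:6]], axis=1),
                "anchor": anc_g[ai5],
                "cls": tt5[:, 1].astype(int),
            }
        )
    return out


def detection_loss(pred_maps, targets, anchors, strides, nc: int = 1,
                   weights: LossWeights | None = None):
    """Weighted positioning + confidence + classification loss.

    pred_maps: raw head outputs, one (N, na*(nc+5), H, W) tensor per
    scale.  targets: (T, 6) normalized rows as in :func:`build_targets`.
    Returns (total, dict of detached components).
    """
    weights = weights or LossWeights()
    n = pred_maps[0].shape[0]
    na = len(anchors[0])
    no = nc + 5
    grids = [(m.shape[2], m.shape[3]) for m in pred_maps]
    assigns = build_targets(targets, np.asarray(anchors, np.float32), strides, grids)
    lbox = Tensor(0.0)
    lobj = Tensor(0.0)
    lcls = Tensor(0.0)
    n_matched = 0
    for si, (pm, asn) in enumerate(zip(pred_maps, assigns)):
        ny, nx = grids[si]
        p = ag.transpose(ag.reshape(pm, (n, na, no, ny, nx)), (0, 1, 3, 4, 2))
        tobj = np.zeros((n, na, ny, nx), dtype=np.float32)
        if asn is not None and len(asn["b"]):
            idx = (asn["b"], asn["a"], asn["gj"], asn["gi"])
            ps = p[idx]                                   # (M, no)
            pxy = ag.sigmoid(ps[:, 0:2]) * 2.0 - 0.5
            cell = np.stack([asn["gi"], asn["gj"]], axis=1).astype(np.float32)
            pxy = pxy + Tensor(cell)
            pwh = (ag.sigmoid(ps[:, 2:4]) * 2.0) ** 2.0 * Tensor(asn["anchor"])
            pbox = ag.concat([pxy, pwh], axis=1)
            l = siou_loss_tensor(pbox, asn["tbox"])
            lbox = lbox + ag.tmean(l)
            n_matched += len(asn["b"])
            sim = np.clip(1.0 - l.data, 0.0, 1.0)
            np.maximum.at(tobj, idx, sim)
            if nc > 1:
                tcls = np.zeros((len(asn["cls"]), nc), dtype=np.float32)
                tcls[np.arange(len(asn["cls"])), asn["cls"]] = 1.0
                lcls = lcls + ag.tmean(bce_with_logits(ps[:, 5:], tcls))
        obj_logits = p[:, :, :, :, 4]
        lobj = lobj + OBJ_BALANCE[si] * ag.tmean(bce_with_logits(obj_logits, tobj))
    total = weights.box * lbox + weights.obj * lobj + weights.cls * lcls
    comps = {
        "box": float(lbox.data),
        "obj": float(lobj.data),
        "cls": float(lcls.data),
        "total": float(total.data),
        "matched": n_matched,
    }
    return total, comps
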