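"""Detection evaluation: greedy IoU matching, precision/recall, average
precision and mean average precision.

Percentages follow the convention of the surrounding literature:
P = TP/(TP+FP) x 100, R = TP/(TP+FN) x 100, AP integrates the precision
envelope over recall (all-point interpolation) and is reported on a
0-100 scale; mAP is the arithmetic class mean and equals AP in the
single-class fruit setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionSet", "PRCurve", "box_iou_matrix", "match",
    "precision_recall", "average_precision", "pr_curve", "mean_ap",
    "evaluate",
]


@dataclass
class DetectionSet:
    """Predictions and ground truth for one image.

    Boxes are (cx, cy, w, h), any consistent units; confidences in [0, 1].
    """
    pred_boxes: np.ndarray      # (P, 4)
    pred_conf: np.ndarray       # (P,)
    pred_class: np.ndarray      # (P,)
    gt_boxes: np.ndarray        # (G, 4)
    gt_class: np.ndarray        # (G,)

    def __post_init__(self):
        self.pred_boxes = np.asarray(self.pred_boxes, dtype=float).reshape(-1, 4)
        self.pred_conf = np.asarray(self.pred_conf, dtype=float).reshape(-1)
        self.pred_class = np.asarray(self.pred_class, dtype=int).reshape(-1)
        self.gt_boxes = np.asarray(self.gt_boxes, dtype=float).reshape(-1, 4)
        self.gt_class = np.asarray(self.gt_class, dtype=int).reshape(-1)
        if np.any((self.pred_conf < 0) | (self.pred_conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    conf: np.ndarray
    ap: float = 0.0


def _cxcywh_to_corners(b: np.ndarray) -> np.ndarray:
    out = np.empty_like(b)
    out[:, 0] = b[:, 0] - b[:, 2] / 2
    out[:, 1] = b[:, 1] - b[:, 3] / 2
    out[:, 2] = b[:, 0] + b[:, 2] / 2
    out[:, 3] = b[:, 1] + b[:, 3] / 2
    return out


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) and (M,4) center-size boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ca, cb = _cxcywh_to_corners(np.asarray(a, float)), _cxcywh_to_corners(np.asarray(b, float))
    tl = np.maximum(ca[:, None, :2], cb[None, :, :2])
    br = np.minimum(ca[:, None, 2:], cb[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (ca[:, 2] - ca[:, 0]) * (ca[:, 3] - ca[:, 1])
    area_b = (cb[:, 2] - cb[:, 0]) * (cb[:, 3] - cb[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-12)


def match(dets: DetectionSet, iou_threshold: float = 0.5):
    """Greedy confidence-ordered matching: each detection claims the
    unmatched same-class ground truth of highest IoU >= threshold.

    Returns (tp_flags aligned with detections sorted by descending
    confidence, sorted confidences, fn_count).  Ties in confidence keep
    input order (non-semantic).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("IoU threshold must lie in (0, 1)")
    order = np.argsort(-dets.pred_conf, kind="stable")
    iou_m = box_iou_matrix(dets.pred_boxes[order], dets.gt_boxes)
    tp = np.zeros(len(order), dtype=bool)
    taken = np.zeros(len(dets.gt_boxes), dtype=bool)
    for i, det_idx in enumerate(order):
        cls = dets.pred_class[det_idx]
        cand = np.where((~taken) & (dets.gt_class == cls) & (iou_m[i] >= iou_threshold))[0]
        if len(cand):
            j = cand[np.argmax(iou_m[i, cand])]
            taken[j] = True
            tp[i] = True
    fn = int((~taken).sum())
    return tp, dets.pred_conf[order], fn


def precision_recall(tp_flags: np.ndarray, fn_count: int):
    """Operating-point P and R in percent; empty denominators give 0."""
    tp = int(np.sum(tp_flags))
    fp = int(len(tp_flags) - tp)
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn_count) if tp + fn_count else 0.0
    return p, r


def pr_curve(tp_flags: np.ndarray, confs: np.ndarray, n_gt: int) -> PRCurve:
    """Confidence-sweep precision/recall with all-point interpolated AP."""
    if len(tp_flags) == 0 or n_gt == 0:
        return PRCurve(np.zeros(0), np.zeros(0), np.zeros(0), 0.0)
    order = np.argsort(-confs, kind="stable")
    tp_c = np.cumsum(tp_flags[order])
    fp_c = np.cumsum(~np.asarray(tp_flags, bool)[order])
    recall = tp_c / n_gt
    precision = tp_c / (tp_c + fp_c)
    curve = PRCurve(precision, recall, confs[order])
    curve.ap = average_precision(curve)
    return curve


def average_precision(curve: PRCurve, eleven_point: bool = False) -> float:
    """Area under the monotone precision envelope, in percent.

    All-point interpolation by default; the 11-point variant is kept for
    sensitivity checks.
    """
    if len(curve.recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [1.0]])
    p = np.concatenate([[1.0], curve.precision, [0.0]])
    env = np.flip(np.maximum.accumulate(np.flip(p)))
    if eleven_point:
        pts = np.interp(np.linspace(0, 1, 11), r, env)
        return float(100.0 * pts.mean())
    idx = np.where(r[1:] != r[:-1])[0]
    return float(100.0 * np.sum((r[idx + 1] - r[idx]) * env[idx + 1]))


def plot_pr_curve(curve: PRCurve, path, title: str = "Precision-recall"):
    """Render a PR curve to PNG (optional reporting output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.recall, curve.precision, drawstyle="steps-post")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"{title} (AP {curve.ap:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mean_ap(per_class_ap) -> float:
    per_class_ap = list(per_class_ap)
    if not per_class_ap:
        raise ValueError("need at least one class AP")
    return float(np.mean(per_class_ap))


def evaluate(det_sets, iou_threshold: float = 0.5, classes=None):
    """Pool detections over images and compute per-class AP, mAP, and the
    operating point (P, R) at the confidence maximizing F1.

    The single reported P/R pair is a convention: the evaluation sweep
    produces a full curve, and the operating threshold is chosen where
    F1 peaks.
    """
    det_sets = list(det_sets)
    if classes is None:
        classes = sorted(
            {int(c) for d in det_sets for c in d.gt_class}
            | {int(c) for d in det_sets for c in d.pred_class}
        ) or [0]
    per_class = {}
    for cls in classes:
        flags, confs, n_gt = [], [], 0
        for d in det_sets:
            keep = d.pred_class == cls
            sub = DetectionSet(
                d.pred_boxes[keep], d.pred_conf[keep], d.pred_class[keep],
                d.gt_boxes[d.gt_class == cls], d.gt_class[d.gt_class == cls],
            )
            tp, cf, _ = match(sub, iou_threshold)
            flags.append(tp)
            confs.append(cf)
            n_gt += len(sub.gt_boxes)
        flags = np.concatenate(flags) if flags else np.zeros(0, bool)
        confs = np.concatenate(confs) if confs else np.zeros(0)
        curve = pr_curve(flags, confs, n_gt)
        per_class[cls] = curve
    aps = [per_class[c].ap for c in classes]
    m_ap = mean_ap(aps)
    # operating point: F1-maximizing confidence over the pooled sweep
    best = (0.0, 0.0, 0.0)  # (f1, P, R)
    for c in classes:
        cv = per_class[c]
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = 2 * cv.precision * cv.recall / np.maximum(cv.precision + cv.recall, 1e-12)
        if len(f1) and np.nanmax(f1) > best[0]:
            i = int(np.nanargmax(f1))
            best = (float(f1[i]), 100.0 * float(cv.precision[i]), 100.0 * float(cv.recall[i]))
    return {
        "map": m_ap,
        "ap_per_class": {int(c): float(per_class[c].ap) for c in classes},
        "precision": best[1],
        "recall": best[2],
        "curves": per_class,
    }
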