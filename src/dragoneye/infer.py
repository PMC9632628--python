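"""Inference path: decode raw head maps, confidence filter, NMS,
letterbox-inverse mapping back to the original frame."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .data import letterbox, unletterbox_boxes

__all__ = ["decode_predictions", "nms", "detect_image", "detect_array"]


def _sigmoid(x):
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def decode_predictions(pred_maps, anchors, strides, nc: int = 1):
    """Raw (N, na*(nc+5), H, W) maps -> per-image (boxes_px, conf, cls).

    Box decode mirrors the training parameterization: centers
    (2*sig - 0.5 + cell) * stride, extents (2*sig)^2 * anchor.
    Confidence is objectness times the best class score."""
    na = len(anchors[0])
    no = nc + 5
    n = pred_maps[0].shape[0]
    boxes, confs, clss = [[] for _ in range(n)], [[] for _ in range(n)], [[] for _ in range(n)]
    for pm, anc, stride in zip(pred_maps, anchors, strides):
        arr = pm.data if hasattr(pm, "data") else pm
        _, _, ny, nx = arr.shape
        p = arr.reshape(n, na, no, ny, nx).transpose(0, 1, 3, 4, 2)
        p = _sigmoid(p)
        gy, gx = np.mgrid[0:ny, 0:nx]
        cx = (p[..., 0] * 2.0 - 0.5 + gx) * stride
        cy = (p[..., 1] * 2.0 - 0.5 + gy) * stride
        anc = np.asarray(anc, dtype=np.float32)
        w = (p[..., 2] * 2.0) ** 2 * anc[:, 0][None, :, None, None]
        h = (p[..., 3] * 2.0) ** 2 * anc[:, 1][None, :, None, None]
        obj = p[..., 4]
        cls_scores = p[..., 5:]
        best_cls = cls_scores.argmax(axis=-1)
        conf = obj * np.take_along_axis(cls_scores, best_cls[..., None], axis=-1)[..., 0]
        for i in range(n):
            boxes[i].append(
                np.stack([cx[i].ravel(), cy[i].ravel(), w[i].ravel(), h[i].ravel()], axis=1)
            )
            confs[i].append(conf[i].ravel())
            clss[i].append(best_cls[i].ravel())
    return [
        (np.concatenate(boxes[i]), np.concatenate(confs[i]), np.concatenate(clss[i]))
        for i in range(n)
    ]


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45):
    """Greedy class-agnostic non-maximum suppression on (cx, cy, w, h)
    boxes; returns kept indices in descending score order."""
    if len(boxes) == 0:
        return np.zeros(0, dtype=int)
    x1 = boxes[:, 0] - boxes[:, 2] / 2
    y1 = boxes[:, 1] - boxes[:, 3] / 2
    x2 = boxes[:, 0] + boxes[:, 2] / 2
    y2 = boxes[:, 1] + boxes[:, 3] / 2
    areas = (x2 - x1) * (y2 - y1)
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        iw = np.clip(np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest]), 0, None)
        ih = np.clip(np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest]), 0, None)
        inter = iw * ih
        iou = inter / (areas[i] + areas[rest] - inter + 1e-12)
        order = rest[iou <= iou_threshold]
    return np.asarray(keep, dtype=int)


def detect_array(graph, img: np.ndarray, input_size: int = 640,
                 conf_threshold: float = 0.25, iou_nms: float = 0.45):
    """Detect on one (H, W, 3) uint8 array; boxes returned in original
    pixel coordinates as (cx, cy, w, h)."""
    canvas, r, pad = letterbox(img, input_size)
    x = canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    graph.eval()
    maps = graph.forward(x)
    # anchor priors are defined at 640-pixel input; rescale to match the
    # working resolution (the training loop uses the same convention)
    anchors = graph.blocks[-1].anchors * (input_size / 640.0)
    (boxes, conf, cls), = decode_predictions(maps, anchors, graph.strides, nc=graph.nc)
    keep = conf > conf_threshold  # strict: saturated scores never pass 1.0
    boxes, conf, cls = boxes[keep], conf[keep], cls[keep]
    keep = nms(boxes, conf, iou_nms)
    boxes, conf, cls = boxes[keep], conf[keep], cls[keep]
    boxes = unletterbox_boxes(boxes, r, pad, img.shape)
    return boxes, conf, cls


def detect_image(graph, path, **kw):
    img = np.asarray(Image.open(Path(path)).convert("RGB"))
    return detect_array(graph, img, **kw)
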