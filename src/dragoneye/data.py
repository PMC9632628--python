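"""Dataset access: normalized-label text files, letterbox resize, mosaic."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .orchard import read_label_file

__all__ = ["letterbox", "unletterbox_boxes", "DetectionDataset", "load_dataset_yaml"]


def letterbox(img: np.ndarray, new_size: int, pad_value: int = 114):
    """Aspect-preserving resize with gray padding to a square canvas.

    Returns (canvas, ratio, (dw, dh)) where dw/dh are the left/top pads."""
    h0, w0 = img.shape[:2]
    r = min(new_size / h0, new_size / w0)
    w1, h1 = int(round(w0 * r)), int(round(h0 * r))
    if (w1, h1) != (w0, h0):
        img = np.asarray(Image.fromarray(img).resize((w1, h1), Image.BILINEAR))
    canvas = np.full((new_size, new_size, 3), pad_value, dtype=np.uint8)
    dw, dh = (new_size - w1) // 2, (new_size - h1) // 2
    canvas[dh : dh + h1, dw : dw + w1] = img
    return canvas, r, (dw, dh)


def unletterbox_boxes(boxes_px: np.ndarray, ratio: float, pad, orig_shape):
    """Map (cx, cy, w, h) pixel boxes from the letterboxed canvas back into
    the original frame, clipped to its bounds."""
    if len(boxes_px) == 0:
        return boxes_px
    dw, dh = pad
    h0, w0 = orig_shape[:2]
    out = boxes_px.copy().astype(float)
    out[:, 0] = (out[:, 0] - dw) / ratio
    out[:, 1] = (out[:, 1] - dh) / ratio
    out[:, 2] /= ratio
    out[:, 3] /= ratio
    x1 = np.clip(out[:, 0] - out[:, 2] / 2, 0, w0)
    y1 = np.clip(out[:, 1] - out[:, 3] / 2, 0, h0)
    x2 = np.clip(out[:, 0] + out[:, 2] / 2, 0, w0)
    y2 = np.clip(out[:, 1] + out[:, 3] / 2, 0, h0)
    out[:, 0], out[:, 1] = (x1 + x2) / 2, (y1 + y2) / 2
    out[:, 2], out[:, 3] = x2 - x1, y2 - y1
    return out


def load_dataset_yaml(path):
    doc = yaml.safe_load(Path(path).read_text())
    root = Path(doc.get("path", Path(path).parent))
    return {
        "root": root,
        "train": root / doc["train"],
        "val": root / doc["val"],
        "nc": int(doc.get("nc", 1)),
        "names": doc.get("names", {0: "fruit"}),
    }


class DetectionDataset:
    """Images plus normalized center-size labels for one split."""

    def __init__(self, images_dir, input_size: int = 640):
        self.images_dir = Path(images_dir)
        self.labels_dir = Path(str(self.images_dir).replace("images", "labels"))
        self.input_size = input_size
        self.paths = sorted(
            p for p in self.images_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not self.paths:
            raise FileNotFoundError(f"no images under {self.images_dir}")

    def __len__(self):
        return len(self.paths)

    def load_raw(self, i: int):
        img = np.asarray(Image.open(self.paths[i]).convert("RGB"))
        lbl = self.labels_dir / (self.paths[i].stem + ".txt")
        boxes = np.array(read_label_file(lbl), dtype=np.float64).reshape(-1, 5) \
            if lbl.exists() else np.zeros((0, 5))
        return img, boxes

    def __getitem__(self, i: int):
        """Letterboxed image in (3, S, S) float [0,1] plus (cls, cx, cy, w, h)
        labels normalized to the canvas."""
        img, boxes = self.load_raw(i)
        h0, w0 = img.shape[:2]
        canvas, r, (dw, dh) = letterbox(img, self.input_size)
        s = self.input_size
        out = boxes.copy()
        if len(out):
            out[:, 1] = (boxes[:, 1] * w0 * r + dw) / s
            out[:, 2] = (boxes[:, 2] * h0 * r + dh) / s
            out[:, 3] = boxes[:, 3] * w0 * r / s
            out[:, 4] = boxes[:, 4] * h0 * r / s
        x = canvas.astype(np.float32).transpose(2, 0, 1) / 255.0
        return x, out

    def mosaic(self, indices, rng: np.random.Generator):
        """Four-image mosaic at the working resolution: each tile is a
        letterboxed image, labels remapped into its quadrant."""
        s = self.input_size
        half = s // 2
        canvas = np.full((3, s, s), 114 / 255.0, dtype=np.float32)
        all_boxes = []
        for k, i in enumerate(indices[:4]):
            img, boxes = self.load_raw(i)
            h0, w0 = img.shape[:2]
            tile, r, (dw, dh) = letterbox(img, half)
            ox, oy = (k % 2) * half, (k // 2) * half
            canvas[:, oy : oy + half, ox : ox + half] = (
                tile.astype(np.float32).transpose(2, 0, 1) / 255.0
            )
            if len(boxes):
                b = boxes.copy()
                b[:, 1] = (boxes[:, 1] * w0 * r + dw + ox) / s
                b[:, 2] = (boxes[:, 2] * h0 * r + dh + oy) / s
                b[:, 3] = boxes[:, 3] * w0 * r / s
                b[:, 4] = boxes[:, 4] * h0 * r / s
                all_boxes.append(b)
        boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 5))
        # drop slivers that fell outside their tile after remapping
        keep = (boxes[:, 3] > 0.004) & (boxes[:, 4] > 0.004)
        return canvas, boxes[keep]
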