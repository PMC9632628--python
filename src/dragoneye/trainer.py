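"""Seeded training and validation loops.

The optimizer is stochastic gradient descent with momentum 0.937 and an
exponential per-epoch learning-rate decay (factor 0.9 as the default
attenuation coefficient); batch size, epoch count, input size and loss
weights all live in :class:`TrainConfig`.  Every source of randomness —
weight init, shuffling, mosaic composition — flows from the single
config seed, so a rerun reproduces epoch losses exactly.  Checkpoints
embed the model configuration and are self-describing.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import architecture as arch
from .autograd import SGD, Tensor
from .data import DetectionDataset, load_dataset_yaml
from .infer import detect_array
from .loss import LossWeights, detection_loss
from .metrics import DetectionSet, evaluate

__all__ = ["TrainConfig", "train", "validate", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 300
    momentum: float = 0.937
    initial_lr: float = 0.001
    lr_decay: float = 0.9          # exponential per-epoch attenuation
    input_size: int = 640
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    mosaic: bool = True
    warmup_epochs: int = 3
    freeze_bn_after: int | None = None  # epoch to fix batch-norm statistics
    grad_clip: float = 10.0             # global gradient-norm ceiling
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        for name in ("batch_size", "epochs", "momentum", "initial_lr", "lr_decay", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def refresh_bn_stats(graph, ds: DetectionDataset, cfg: TrainConfig,
                     rng: np.random.Generator, max_batches: int = 8):
    """Recompute batch-norm running statistics under the final weights.

    During optimization the running averages trail the moving weights;
    a few plain forward passes with cumulative averaging align them, so
    eval-mode inference sees the same normalization training did."""
    from .nn_blocks import BatchNorm2d

    bns = [m for m in graph.modules() if isinstance(m, BatchNorm2d)]
    was_training = graph.training
    graph.eval()
    for bn in bns:
        bn.calibrating = True
    # fixed-point iteration: each pass normalizes with the current running
    # estimates while recording every layer's true input statistics, so the
    # compounding shift of switching all layers at once dies out
    for _ in range(3):
        seen = 0
        for imgs, _ in _iter_batches(ds, cfg, rng):
            for bn in bns:
                bn.momentum = 1.0 / (seen + 1)
            graph.forward(imgs)
            seen += 1
            if seen >= max_batches:
                break
        for bn in bns:  # E[x^2] accumulator -> population variance
            bn.running_var[...] = np.maximum(
                bn.running_var - bn.running_mean**2, 1e-6
            )
    for bn in bns:
        bn.calibrating = False
        bn.momentum = 0.03
    graph.train(was_training)


def save_checkpoint(path, graph, cfg: TrainConfig, meta=None):
    state = graph.state_dict()
    state["__train_config__"] = np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8
    )
    state["__meta__"] = np.frombuffer(json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, n_classes=None):
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    cfg = TrainConfig(**json.loads(bytes(state.pop("__train_config__")).decode()))
    meta = json.loads(bytes(state.pop("__meta__")).decode())
    nc = meta.get("nc", 1)
    if n_classes is not None and n_classes != nc:
        raise ValueError(f"checkpoint trained with {nc} classes, dataset has {n_classes}")
    graph = arch.build(n_classes=nc)
    graph.load_state_dict(state)
    return graph, cfg, meta


def _stratified_subset(paths, k: int):
    """Evenly spaced selection across the (name-sorted) split, so a small
    subset spans the lighting regimes instead of exhausting the first one."""
    if k >= len(paths):
        return list(paths)
    idx = np.unique(np.round(np.linspace(0, len(paths) - 1, k)).astype(int))
    return [paths[i] for i in idx]


def _iter_batches(ds: DetectionDataset, cfg: TrainConfig, rng: np.random.Generator):
    order = rng.permutation(len(ds))
    bs = min(cfg.batch_size, len(ds))
    for i in range(0, len(order) - bs + 1, bs):
        idx = order[i : i + bs]
        imgs, tgts = [], []
        for k, j in enumerate(idx):
            if cfg.mosaic and rng.random() < 0.5 and len(ds) >= 4:
                extra = rng.integers(0, len(ds), size=3)
                x, b = ds.mosaic([j, *extra], rng)
            else:
                x, b = ds[j]
            imgs.append(x)
            if len(b):
                t = np.zeros((len(b), 6), dtype=np.float32)
                t[:, 0] = k
                t[:, 1:] = b[:, [0, 1, 2, 3, 4]]
                tgts.append(t)
        yield np.stack(imgs), (np.concatenate(tgts) if tgts else np.zeros((0, 6), np.float32))


def train(data, cfg: TrainConfig, out_dir, graph=None, subset=None, log_every=1,
          progress=None):
    """Run the training loop; returns (graph, history).

    `data` is a dataset YAML path or an images/train directory; `subset`
    optionally restricts to the first k images (overfit smoke checks).
    Writes line-delimited JSON logs and a final self-describing
    checkpoint under `out_dir`.  Aborts on non-finite loss.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(data)
    if data.suffix in (".yaml", ".yml"):
        info = load_dataset_yaml(data)
        train_dir, nc = info["train"], info["nc"]
    else:
        train_dir, nc = data, 1
    ds = DetectionDataset(train_dir, cfg.input_size)
    if subset:
        ds.paths = _stratified_subset(ds.paths, subset)
    rng = np.random.default_rng(cfg.seed)
    if graph is None:
        graph = arch.build(n_classes=nc, seed=cfg.seed)
    graph.train()
    anchors = graph.blocks[-1].anchors * (cfg.input_size / 640.0)
    opt = SGD(graph.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum)
    weights = LossWeights(cfg.box_weight, cfg.obj_weight, cfg.cls_weight)
    history = []
    frozen = False
    no_mosaic = TrainConfig(**{**asdict(cfg), "mosaic": False})
    log_path = out / "train_log.jsonl"
    with log_path.open("w") as log:
        log.write(json.dumps({"config": asdict(cfg), "n_images": len(ds)}) + "\n")
        for epoch in range(cfg.epochs):
            if cfg.freeze_bn_after is not None and epoch == cfg.freeze_bn_after:
                # small-batch training co-adapts to per-batch statistics;
                # fixing them here lets the remaining epochs fit against the
                # exact normalization inference will use
                refresh_bn_stats(graph, ds, no_mosaic, rng)
                from .nn_blocks import BatchNorm2d
                for m in graph.modules():
                    if isinstance(m, BatchNorm2d):
                        object.__setattr__(m, "training", False)
                frozen = True
            opt.lr = cfg.initial_lr * cfg.lr_decay ** epoch
            if epoch < cfg.warmup_epochs:  # linear ramp stabilizes early steps
                opt.lr *= (epoch + 1) / (cfg.warmup_epochs + 1)
            sums, nb = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}, 0
            t0 = time.time()
            for imgs, tgts in _iter_batches(ds, cfg, rng):
                total, comps = detection_loss(
                    graph.forward(imgs), tgts, anchors, graph.strides, nc, weights
                )
                # gradient scales with batch size (family convention), so the
                # learning rate is batch-size independent
                total = total * float(imgs.shape[0])
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {comps}"
                    )
                opt.zero_grad()
                total.backward()
                if cfg.grad_clip:
                    sq = sum(
                        float((p.grad ** 2).sum())
                        for p in opt.params if p.grad is not None
                    )
                    norm = sq ** 0.5
                    if norm > cfg.grad_clip:
                        scale = cfg.grad_clip / (norm + 1e-12)
                        for p in opt.params:
                            if p.grad is not None:
                                p.grad *= scale
                opt.step()
                for k in sums:
                    sums[k] += comps[k]
                nb += 1
            rec = {
                "epoch": epoch,
                "lr": opt.lr,
                "seconds": round(time.time() - t0, 2),
                **{k: round(v / max(nb, 1), 5) for k, v in sums.items()},
            }
            history.append(rec)
            if epoch % log_every == 0 or epoch == cfg.epochs - 1:
                log.write(json.dumps(rec) + "\n")
                log.flush()
            if progress:
                progress(rec)
    if not frozen:
        refresh_bn_stats(graph, ds, no_mosaic, rng)
    save_checkpoint(out / "checkpoint.npz", graph, cfg, meta={"nc": nc})
    return graph, history


def validate(graph, images_dir, input_size: int = 640, conf_threshold: float = 0.001,
             iou_nms: float = 0.45, iou_match: float = 0.5, subset=None,
             by_scene: bool = True):
    """Detect on a split and score with the P/R/AP/mAP machinery; scenes
    are read from the image-name prefix (regime_xxxx) when present."""
    ds = DetectionDataset(images_dir, input_size)
    if subset:
        ds.paths = _stratified_subset(ds.paths, subset)
    det_sets, scenes = [], []
    for i in range(len(ds)):
        img, gt = ds.load_raw(i)
        h0, w0 = img.shape[:2]
        boxes, conf, cls = detect_array(
            graph, img, input_size, conf_threshold, iou_nms
        )
        gt_px = gt.copy()
        if len(gt_px):
            gt_px[:, 1] *= w0
            gt_px[:, 2] *= h0
            gt_px[:, 3] *= w0
            gt_px[:, 4] *= h0
        det_sets.append(
            DetectionSet(boxes, np.clip(conf, 0, 1), cls, gt_px[:, 1:5], gt_px[:, 0])
        )
        scenes.append(ds.paths[i].stem.rsplit("_", 1)[0])
    overall = evaluate(det_sets, iou_match)
    report = {
        "map": overall["map"],
        "precision": overall["precision"],
        "recall": overall["recall"],
        "ap_per_class": overall["ap_per_class"],
        "n_images": len(det_sets),
    }
    if by_scene:
        per_scene = {}
        for scene in sorted(set(scenes)):
            sel = [d for d, s in zip(det_sets, scenes) if s == scene]
            per_scene[scene] = evaluate(sel, iou_match)["map"]
        report["map_per_scene"] = per_scene
    return report
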