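"""Training and evaluation drivers.

Loss follows the YOLO-family default recipe: task-aligned assignment of
feature-map cells to targets, binary cross-entropy against aligned soft
labels, complete-IoU loss on decoded boxes and a distribution loss on
the per-side distance bins, weighted 7.5 / 0.5 / 1.5. The optimizer is
SGD with momentum, weight decay on convolution weights only, linear
warmup of learning rate and momentum, and a linear lr0 -> lrf schedule.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data_io import AugmentParams, augment, letterbox, load_split, read_manifest
from .metrics import Detection, GroundTruthBox, MetricsReport, iou_matrix, map_suite
from .network import (Detector, ModelConfig, build_model, decode_predictions,
                      nms, save_checkpoint)

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "detection_loss",
    "train",
    "evaluate",
    "LOSS_WEIGHTS",
]

# box / cls / dfl weights of the default recipe
LOSS_WEIGHTS = (7.5, 0.5, 1.5)
ASSIGN_TOPK = 10
ASSIGN_ALPHA = 0.5
ASSIGN_BETA = 6.0


@dataclass
class TrainConfig:
    epochs: int = 200
    batch: int = 16
    lr0: float = 0.01
    lrf: float = 0.01          # final learning rate (absolute, not a fraction)
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    warmup_bias_lr: float = 0.1
    imgsz: int = 640
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        for name in ("epochs", "batch", "lr0", "lrf", "momentum",
                     "weight_decay", "warmup_momentum", "warmup_bias_lr", "imgsz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")


@dataclass
class LossBreakdown:
    box_loss: float
    cls_loss: float
    dfl_loss: float
    total: float
    tensor: object = None  # autograd node of the weighted total

    def finite(self) -> bool:
        return all(math.isfinite(v) for v in
                   (self.box_loss, self.cls_loss, self.dfl_loss, self.total))


def _anchor_grid(cfg: ModelConfig, level_hw):
    """Pixel-space cell centers and per-anchor strides, all levels stacked."""
    centers, strides = [], []
    for (h, w), s in zip(level_hw, cfg.strides):
        cx = (np.arange(w) + 0.5) * s
        cy = (np.arange(h) + 0.5) * s
        gx, gy = np.meshgrid(cx, cy)
        centers.append(np.stack([gx.reshape(-1), gy.reshape(-1)], axis=1))
        strides.append(np.full(h * w, s, float))
    return np.concatenate(centers, axis=0), np.concatenate(strides)


def _flatten_raw(raw, cfg: ModelConfig):
    """Stack per-level maps into (N, A, 4, regmax) reg logits and
    (N, A, nc) cls logits (autograd tensors), plus level shapes."""
    regs, clss, level_hw = [], [], []
    rm, nc = cfg.regmax, cfg.num_classes
    for reg, cls in raw:
        n, _, h, w = reg.shape
        level_hw.append((h, w))
        regs.append(reg.reshape(n, 4, rm, h * w).transpose(0, 3, 1, 2))
        clss.append(cls.reshape(n, nc, h * w).transpose(0, 2, 1))
    return nn.concat(regs, axis=1), nn.concat(clss, axis=1), level_hw


def _assign(scores, pred_boxes, anchors, gt_boxes, gt_cls):
    """Task-aligned assignment for one image (all numpy, detached).

    Returns (fg_mask (A,), assigned_gt (A,), cls_target (A, nc)).
    """
    a = anchors.shape[0]
    nc = scores.shape[1]
    m = gt_boxes.shape[0]
    cls_target = np.zeros((a, nc))
    fg = np.zeros(a, bool)
    assigned = np.full(a, -1)
    if m == 0:
        return fg, assigned, cls_target
    iou_am = iou_matrix(pred_boxes, gt_boxes)                    # (A, M)
    inside = ((anchors[:, 0:1] > gt_boxes[None, :, 0]) &
              (anchors[:, 0:1] < gt_boxes[None, :, 2]) &
              (anchors[:, 1:2] > gt_boxes[None, :, 1]) &
              (anchors[:, 1:2] < gt_boxes[None, :, 3]))
    metric = (scores[:, gt_cls] ** ASSIGN_ALPHA) * (iou_am ** ASSIGN_BETA)
    metric = np.where(inside, metric, 0.0)
    # top-k candidate anchors per gt
    k = min(ASSIGN_TOPK, a)
    cand = np.zeros_like(metric, bool)
    topk_idx = np.argpartition(-metric, k - 1, axis=0)[:k]
    cand[topk_idx, np.arange(m)[None, :]] = True
    cand &= metric > 0
    # an anchor claimed by several gts goes to the one with the best metric
    masked = np.where(cand, metric, -1.0)
    best_gt = masked.argmax(axis=1)
    fg = masked[np.arange(a), best_gt] > 0
    assigned[fg] = best_gt[fg]
    # aligned soft labels, normalized per gt
    for g in range(m):
        sel = fg & (assigned == g)
        if not sel.any():
            continue
        t = metric[sel, g]
        norm = t * (iou_am[sel, g].max() / (t.max() + 1e-9))
        cls_target[sel, gt_cls[g]] = norm
    return fg, assigned, cls_target


def _ciou_loss(pb, gt):
    """Complete-IoU loss (1 - CIoU) between predicted boxes (autograd
    tensor, (K,4) xyxy) and constant ground-truth boxes."""
    eps = 1e-7
    g = np.asarray(gt, float)
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    px1, py1, px2, py2 = pb[:, 0], pb[:, 1], pb[:, 2], pb[:, 3]
    iw = px2.minimum(gx2) - px1.maximum(gx1)
    ih = py2.minimum(gy2) - py1.maximum(gy1)
    inter = iw.clip(0.0, np.inf) * ih.clip(0.0, np.inf)
    pw = (px2 - px1).clip(eps, np.inf)
    ph = (py2 - py1).clip(eps, np.inf)
    area_p = pw * ph
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter + eps
    iou = inter / union
    # enclosing box diagonal
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - gx1 - gx2) * 0.5) ** 2 + ((py1 + py2 - gy1 - gy2) * 0.5) ** 2
    gw = np.maximum(gx2 - gx1, eps)
    gh = np.maximum(gy2 - gy1, eps)
    atan_diff = nn.Tensor(np.arctan(gw / gh)) - (pw / ph).atan()
    v = atan_diff * atan_diff * (4.0 / math.pi ** 2)
    alpha = nn.Tensor(v.data / (1.0 - iou.data + v.data + eps))  # detached
    ciou = iou - rho2 / c2 - alpha * v
    return 1.0 - ciou


def detection_loss(raw, targets, cfg: ModelConfig,
                   weights=LOSS_WEIGHTS) -> LossBreakdown:
    """Compute the composite detection loss.

    `raw`: Detector.forward output for a batch of N images.
    `targets`: list of N arrays (M_i, 5) with rows [class, cx, cy, w, h]
    normalized to [0,1].
    """
    w_box, w_cls, w_dfl = weights
    rm = cfg.regmax
    reg, cls, level_hw = _flatten_raw(raw, cfg)
    n, a = cls.shape[0], cls.shape[1]
    img_h = level_hw[0][0] * cfg.strides[0]
    img_w = level_hw[0][1] * cfg.strides[0]
    anchors, strides = _anchor_grid(cfg, level_hw)

    log_prob = reg.log_softmax(axis=3)                 # (N, A, 4, rm)
    prob = log_prob.exp()
    bins = nn.Tensor(np.arange(rm, dtype=float).reshape(1, 1, 1, rm))
    dist_units = (prob * bins).sum(axis=3)             # stride units
    dist_px = dist_units * nn.Tensor(strides.reshape(1, a, 1))
    ax = nn.Tensor(anchors[None, :, 0])
    ay = nn.Tensor(anchors[None, :, 1])
    # (N, A, 4) xyxy via stacked columns
    with np.errstate(over="ignore"):
        scores_d = 1.0 / (1.0 + np.exp(-cls.data))

    cls_targets = np.zeros((n, a, cfg.num_classes))
    fg_i, fg_a, fg_gtbox, fg_w = [], [], [], []
    px1 = ax - dist_px[:, :, 0]
    py1 = ay - dist_px[:, :, 1]
    px2 = ax + dist_px[:, :, 2]
    py2 = ay + dist_px[:, :, 3]
    pred_boxes_d = np.stack([px1.data, py1.data, px2.data, py2.data], axis=2)

    for i in range(n):
        t = np.asarray(targets[i], float).reshape(-1, 5)
        if t.shape[0] == 0:
            continue
        gt_cls = t[:, 0].astype(int)
        cxcywh = t[:, 1:]
        gt_boxes = np.stack([
            (cxcywh[:, 0] - cxcywh[:, 2] / 2) * img_w,
            (cxcywh[:, 1] - cxcywh[:, 3] / 2) * img_h,
            (cxcywh[:, 0] + cxcywh[:, 2] / 2) * img_w,
            (cxcywh[:, 1] + cxcywh[:, 3] / 2) * img_h,
        ], axis=1)
        fg, assigned, ct = _assign(scores_d[i], pred_boxes_d[i], anchors,
                                   gt_boxes, gt_cls)
        cls_targets[i] = ct
        idx = np.flatnonzero(fg)
        if idx.size:
            fg_i.append(np.full(idx.size, i))
            fg_a.append(idx)
            fg_gtbox.append(gt_boxes[assigned[idx]])
            fg_w.append(ct[idx].max(axis=1))

    target_sum = max(float(cls_targets.sum()), 1.0)
    cls_loss = nn.bce_with_logits(cls, cls_targets).sum() / target_sum

    if fg_i:
        ii = np.concatenate(fg_i)
        aa = np.concatenate(fg_a)
        gtb = np.concatenate(fg_gtbox, axis=0)
        wgt = np.concatenate(fg_w)
        wsum = max(float(wgt.sum()), 1e-9)
        pb = nn.concat([
            px1[ii, aa].reshape(-1, 1), py1[ii, aa].reshape(-1, 1),
            px2[ii, aa].reshape(-1, 1), py2[ii, aa].reshape(-1, 1),
        ], axis=1)
        box_loss = (_ciou_loss(pb, gtb) * nn.Tensor(wgt)).sum() / wsum

        # distribution loss: cross-entropy on the two bins bracketing the
        # true (stride-normalized) distance, per side
        st = strides[aa]
        dist_t = np.stack([
            (anchors[aa, 0] - gtb[:, 0]) / st,
            (anchors[aa, 1] - gtb[:, 1]) / st,
            (gtb[:, 2] - anchors[aa, 0]) / st,
            (gtb[:, 3] - anchors[aa, 1]) / st,
        ], axis=1)
        dist_t = np.clip(dist_t, 0.0, rm - 1 - 1e-3)
        lo = np.floor(dist_t).astype(int)
        hi = lo + 1
        w_hi = dist_t - lo
        w_lo = 1.0 - w_hi
        lp = log_prob[ii, aa]                          # (K, 4, rm)
        kk = np.arange(ii.size)[:, None]
        ss = np.arange(4)[None, :]
        ce = -(lp[kk, ss, lo] * nn.Tensor(w_lo) + lp[kk, ss, hi] * nn.Tensor(w_hi))
        dfl_loss = (ce.mean(axis=1) * nn.Tensor(wgt)).sum() / wsum
    else:
        box_loss = nn.Tensor(np.zeros(()))
        dfl_loss = nn.Tensor(np.zeros(()))

    total = box_loss * w_box + cls_loss * w_cls + dfl_loss * w_dfl
    return LossBreakdown(
        box_loss=float(box_loss.data),
        cls_loss=float(cls_loss.data),
        dfl_loss=float(dfl_loss.data),
        total=float(total.data),
        tensor=total,
    )


# ---------------------------------------------------------------------
# optimizer schedule
# ---------------------------------------------------------------------

def _param_groups(model: Detector, tcfg: TrainConfig):
    """weights (decayed) / norm scales (no decay) / biases (warmed up)."""
    decay, no_decay, biases = [], [], []
    for name, p in model.named_parameters():
        if p.data.ndim >= 2:
            decay.append(p)
        elif name.endswith((".bias", ".beta", ".w")):
            biases.append(p)
        else:
            no_decay.append(p)
    return nn.SGD([
        {"params": decay, "lr": tcfg.lr0, "momentum": tcfg.momentum,
         "weight_decay": tcfg.weight_decay},
        {"params": no_decay, "lr": tcfg.lr0, "momentum": tcfg.momentum},
        {"params": biases, "lr": tcfg.lr0, "momentum": tcfg.momentum},
    ])


def lr_at_epoch(tcfg: TrainConfig, epoch: float) -> float:
    """Linear anneal lr0 -> lrf over the training run."""
    if tcfg.epochs <= 1:
        return tcfg.lr0
    frac = min(max(epoch / (tcfg.epochs - 1), 0.0), 1.0)
    return tcfg.lr0 + (tcfg.lrf - tcfg.lr0) * frac


def schedule_at(tcfg: TrainConfig, it: int, steps_per_epoch: int):
    """(lr, bias_lr, momentum) at global iteration `it`."""
    epoch = it / max(steps_per_epoch, 1)
    base = lr_at_epoch(tcfg, epoch)
    warmup_iters = tcfg.warmup_epochs * steps_per_epoch
    if warmup_iters > 0 and it < warmup_iters:
        f = it / warmup_iters
        lr = f * base
        bias_lr = tcfg.warmup_bias_lr + f * (base - tcfg.warmup_bias_lr)
        mom = tcfg.warmup_momentum + f * (tcfg.momentum - tcfg.warmup_momentum)
        return lr, bias_lr, mom
    return base, base, tcfg.momentum


# ---------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------

def _prepare_samples(samples, imgsz: int):
    """Letterbox once; return list of (image float32 CHW /255, targets (M,5))."""
    out = []
    for s in samples:
        lb = letterbox(s.image, s.boxes, imgsz)
        img = lb.image.astype(np.float32).transpose(2, 0, 1) / 255.0
        t = np.array([[b.class_id, b.cx, b.cy, b.w, b.h] for b in lb.boxes],
                     float).reshape(-1, 5)
        out.append((img, t, lb))
    return out


def evaluate_on_samples(model: Detector, prepared,
                        conf_threshold: float = 0.001,
                        iou_threshold: float = 0.45) -> MetricsReport:
    """decode -> NMS -> metric suite over pre-letterboxed samples.

    Images are strung out along x (one large offset per image) so the
    single-pool metric suite never cross-matches between images.
    """
    if not prepared:
        raise ValueError("empty evaluation set")
    model.eval()
    dets, gts = [], []
    imgsz = prepared[0][0].shape[1]
    offset = float(imgsz * 10)
    for i, (img, t, _) in enumerate(prepared):
        raw = model(nn.Tensor(img[None]))
        d = nms(decode_predictions(raw, model.cfg, conf_threshold, imgsz),
                iou_threshold)
        for det in d:
            b = det.box
            dets.append(Detection((b[0] + i * offset, b[1], b[2] + i * offset, b[3]),
                                  det.score, det.class_id))
        for row in t:
            c, cx, cy, w, h = row
            gts.append(GroundTruthBox((
                (cx - w / 2) * imgsz + i * offset, (cy - h / 2) * imgsz,
                (cx + w / 2) * imgsz + i * offset, (cy + h / 2) * imgsz,
            ), int(c)))
    return map_suite(dets, gts)


def evaluate(checkpoint_path, manifest_path, split: str = "val",
             conf_threshold: float = 0.001,
             iou_threshold: float = 0.45, imgsz: int | None = None) -> MetricsReport:
    """Load a checkpoint and score one split of a dataset."""
    from .network import load_checkpoint
    model, header = load_checkpoint(checkpoint_path)
    manifest = read_manifest(manifest_path)
    samples = load_split(manifest, split)
    if not samples:
        raise ValueError(f"split {split!r} of {manifest_path} is empty")
    size = imgsz or header.get("extra", {}).get("imgsz") or 640
    prepared = _prepare_samples(samples, int(size))
    return evaluate_on_samples(model, prepared, conf_threshold, iou_threshold)


def train(model_cfg: ModelConfig, manifest_path, tcfg: TrainConfig,
          out_dir, eval_split: str = "val",
          augment_params: AugmentParams | None = None):
    """Train from scratch; returns (best checkpoint path, per-epoch log).

    Writes `log.jsonl` (one row per epoch: losses + metrics) and keeps
    the checkpoint with the best mAP50-95 on `eval_split`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    train_samples = load_split(manifest, "train")
    if not train_samples:
        raise ValueError("training split is empty")
    try:
        eval_samples = load_split(manifest, eval_split)
    except FileNotFoundError:
        eval_samples = []
    if not eval_samples:
        eval_samples = train_samples

    rng = np.random.default_rng(tcfg.seed)
    model = build_model(model_cfg, seed=tcfg.seed)
    opt = _param_groups(model, tcfg)
    prepared_eval = _prepare_samples(eval_samples, tcfg.imgsz)
    aug = augment_params or AugmentParams()

    nb = max(1, math.ceil(len(train_samples) / tcfg.batch))
    best_map, best_path = -1.0, out_dir / "best.ckpt"
    log_path = out_dir / "log.jsonl"
    log_rows = []
    it = 0
    with log_path.open("w") as log_file:
        for epoch in range(tcfg.epochs):
            t0 = time.time()
            model.train()
            order = rng.permutation(len(train_samples))
            sums = np.zeros(4)
            for b0 in range(0, len(order), tcfg.batch):
                idx = order[b0:b0 + tcfg.batch]
                batch_samples = []
                for j in idx:
                    s = train_samples[j]
                    if tcfg.augment:
                        s = augment(s, aug, seed=int(rng.integers(2 ** 31)))
                    batch_samples.append(s)
                prepared = _prepare_samples(batch_samples, tcfg.imgsz)
                imgs = np.stack([p[0] for p in prepared])
                targets = [p[1] for p in prepared]

                lr, bias_lr, mom = schedule_at(tcfg, it, nb)
                for gi, g in enumerate(opt.groups):
                    g["lr"] = bias_lr if gi == 2 else lr
                    g["momentum"] = mom

                raw = model(nn.Tensor(imgs))
                loss = detection_loss(raw, targets, model_cfg)
                if not loss.finite():
                    raise RuntimeError(
                        f"divergence: non-finite loss at epoch {epoch} "
                        f"(box={loss.box_loss}, cls={loss.cls_loss}, dfl={loss.dfl_loss})")
                opt.zero_grad()
                loss.tensor.backward()
                opt.step()
                sums += (loss.box_loss, loss.cls_loss, loss.dfl_loss, loss.total)
                it += 1

            report = evaluate_on_samples(model, prepared_eval)
            row = {
                "epoch": epoch,
                "box_loss": sums[0] / nb, "cls_loss": sums[1] / nb,
                "dfl_loss": sums[2] / nb, "loss": sums[3] / nb,
                "map50": report.map50, "map50_95": report.map50_95,
                "precision": report.precision, "recall": report.recall,
                "lr": schedule_at(tcfg, it - 1, nb)[0],
                "seconds": round(time.time() - t0, 2),
            }
            log_rows.append(row)
            log_file.write(json.dumps(row) + "\n")
            log_file.flush()
            if report.map50_95 >= best_map:
                best_map = report.map50_95
                save_checkpoint(best_path, model, seed=tcfg.seed, epoch=epoch,
                                extra={"imgsz": tcfg.imgsz,
                                       "map50_95": report.map50_95,
                                       "train_config": asdict(tcfg)})
    save_checkpoint(out_dir / "last.ckpt", model, seed=tcfg.seed,
                    epoch=tcfg.epochs - 1,
                    extra={"imgsz": tcfg.imgsz, "train_config": asdict(tcfg)})
    return best_path, log_rows
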