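"""Detector assembly: inverted-bottleneck backbone, weighted
bidirectional feature-pyramid neck with ghost-conv projections, and an
anchor-free decoupled head with distribution-style box regression.

Coordinate conventions: 0-based pixel coordinates, half-open xyxy boxes.
The three detection levels P3/P4/P5 sit at strides 8/16/32, so input
sizes must be divisible by 32.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .blocks import ConvBNAct, DepthwiseSeparableConv, GhostConv, \
    InvertedBottleneckStage
from .metrics import Detection, iou_matrix

__all__ = [
    "ModelConfig",
    "Detector",
    "build_model",
    "bifpn_fuse",
    "decode_predictions",
    "nms",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_MAGIC",
]

CHECKPOINT_MAGIC = "fruitdet-ckpt-v1"
FUSION_EPS = 1e-4


@dataclass
class ModelConfig:
    num_classes: int = 1
    width_mult: float = 0.5
    stage_channels: tuple = (64, 128, 256, 512)
    stage_blocks: tuple = (1, 2, 2, 1)
    expansion: tuple = (4.0, 4.0, 4.0, 4.0)
    bifpn_channels: int = 96
    bifpn_repeats: int = 2
    regmax: int = 16
    strides: tuple = (8, 16, 32)

    def __post_init__(self):
        problems = []
        if self.num_classes < 1:
            problems.append(f"num_classes must be >= 1, got {self.num_classes}")
        if self.width_mult <= 0:
            problems.append(f"width_mult must be positive, got {self.width_mult}")
        if len(self.stage_channels) != 4 or any(c < 1 for c in self.stage_channels):
            problems.append(f"stage_channels must be 4 positive counts, got {self.stage_channels}")
        if len(self.stage_blocks) != 4 or any(b < 1 for b in self.stage_blocks):
            problems.append(f"stage_blocks must be 4 counts >= 1, got {self.stage_blocks}")
        if isinstance(self.expansion, (int, float)):
            self.expansion = (float(self.expansion),) * 4
        if len(self.expansion) != 4 or any(e <= 0 for e in self.expansion):
            problems.append(f"expansion must be 4 positive reals, got {self.expansion}")
        if self.regmax < 2:
            problems.append(f"regmax must be >= 2, got {self.regmax}")
        if self.bifpn_channels < 2 or self.bifpn_channels % 2:
            problems.append(f"bifpn_channels must be a positive even count, got {self.bifpn_channels}")
        if self.bifpn_repeats < 1:
            problems.append(f"bifpn_repeats must be >= 1, got {self.bifpn_repeats}")
        st = tuple(self.strides)
        if (len(st) != 3 or any(s & (s - 1) for s in st)
                or list(st) != sorted(st) or len(set(st)) != 3):
            problems.append(f"strides must be 3 strictly increasing powers of 2, got {st}")
        if problems:
            raise ValueError("invalid model config: " + "; ".join(problems))

    def scaled_channels(self) -> tuple:
        """Stage widths after width_mult, rounded, kept even and >= 2."""
        out = []
        for c in self.stage_channels:
            v = max(2, int(round(c * self.width_mult)))
            out.append(v + (v % 2))
        return tuple(out)

    @staticmethod
    def from_yaml(path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in ModelConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        for key in ("stage_channels", "stage_blocks", "expansion", "strides"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return ModelConfig(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def bifpn_fuse(inputs, weights, eps: float = FUSION_EPS):
    """Fast normalized fusion: sum_i w_i * I_i / (sum_j w_j + eps) with
    weights clamped non-negative before use.

    `inputs` may be numpy arrays or autograd tensors (all same shape);
    `weights` a sequence or 1-D tensor of per-input scalars.
    """
    if len(inputs) != (weights.size if isinstance(weights, nn.Tensor) else len(weights)):
        raise ValueError("one fusion weight per input is required")
    shapes = {tuple(x.shape) for x in inputs}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
    if isinstance(weights, nn.Tensor):
        w = weights.relu()
        denom = w.sum() + eps
        acc = inputs[0] * (w[0] / denom)
        for i in range(1, len(inputs)):
            acc = acc + inputs[i] * (w[i] / denom)
        return acc
    w = np.clip(np.asarray(weights, float), 0.0, None)
    denom = w.sum() + eps
    acc = inputs[0] * (w[0] / denom)
    for i in range(1, len(inputs)):
        acc = acc + inputs[i] * (w[i] / denom)
    return acc


class FusionNode(nn.Module):
    """Learnable-weight normalized fusion followed by a depthwise-separable conv."""

    def __init__(self, n_inputs: int, channels: int):
        super().__init__()
        self.w = nn.Parameter(np.ones(n_inputs, np.float32))
        self.conv = DepthwiseSeparableConv(channels, channels, kernel=3)

    def forward(self, inputs):
        return self.conv(bifpn_fuse(inputs, self.w))


class BiFPNLayer(nn.Module):
    """One bidirectional round over (P3, P4, P5)."""

    def __init__(self, channels: int):
        super().__init__()
        self.td4 = FusionNode(2, channels)   # P4 + up(P5)
        self.td3 = FusionNode(2, channels)   # P3 + up(P4')
        self.bu4 = FusionNode(3, channels)   # P4 + P4' + down(P3_out)
        self.bu5 = FusionNode(2, channels)   # P5 + down(P4_out)
        self.down3 = DepthwiseSeparableConv(channels, channels, kernel=3, stride=2)
        self.down4 = DepthwiseSeparableConv(channels, channels, kernel=3, stride=2)

    def forward(self, feats):
        p3, p4, p5 = feats
        p4_td = self.td4([p4, p5.upsample_nearest(2)])
        p3_out = self.td3([p3, p4_td.upsample_nearest(2)])
        p4_out = self.bu4([p4, p4_td, self.down3(p3_out)])
        p5_out = self.bu5([p5, self.down4(p4_out)])
        return [p3_out, p4_out, p5_out]


class DetectHead(nn.Module):
    """Decoupled anchor-free head for one level: standard-conv regression
    branch (4*regmax channels) and depthwise-separable classification
    branch (num_classes channels)."""

    def __init__(self, channels: int, num_classes: int, regmax: int):
        super().__init__()
        self.reg = nn.Sequential(
            ConvBNAct(channels, channels, 3),
            ConvBNAct(channels, channels, 3),
            nn.Conv2d(channels, 4 * regmax, 1, bias=True),
        )
        self.cls = nn.Sequential(
            DepthwiseSeparableConv(channels, channels, 3),
            DepthwiseSeparableConv(channels, channels, 3),
            nn.Conv2d(channels, num_classes, 1, bias=True),
        )

    def forward(self, x):
        return self.reg(x), self.cls(x)


class Detector(nn.Module):
    """Backbone -> BiFPN neck -> per-level decoupled heads.

    forward() returns raw predictions: a list over (P3, P4, P5) of
    (regression map, classification logits map) tensor pairs.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.scaled_channels()
        e1, e2, e3, e4 = cfg.expansion
        nc = cfg.bifpn_channels

        self.stem = nn.Sequential(
            ConvBNAct(3, c1, 3, stride=2),
            ConvBNAct(c1, c1, 3, stride=2),
        )
        # stage 1 refines at stride 4; stages 2-4 are the stride-2 entries
        # emitting C3/C4/C5 at strides 8/16/32
        self.stage1 = InvertedBottleneckStage(c1, c1, cfg.stage_blocks[0], e1, stride=1)
        self.stage2 = InvertedBottleneckStage(c1, c2, cfg.stage_blocks[1], e2, stride=2)
        self.stage3 = InvertedBottleneckStage(c2, c3, cfg.stage_blocks[2], e3, stride=2)
        self.stage4 = InvertedBottleneckStage(c3, c4, cfg.stage_blocks[3], e4, stride=2)

        self.lateral3 = GhostConv(c2, nc)
        self.lateral4 = GhostConv(c3, nc)
        self.lateral5 = GhostConv(c4, nc)
        self.bifpn = nn.ModuleList([BiFPNLayer(nc) for _ in range(cfg.bifpn_repeats)])
        self.out3 = GhostConv(nc, nc)
        self.out4 = GhostConv(nc, nc)
        self.out5 = GhostConv(nc, nc)
        self.heads = nn.ModuleList([
            DetectHead(nc, cfg.num_classes, cfg.regmax) for _ in cfg.strides
        ])

    def forward(self, x):
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {x.shape[2:]}")
        x = self.stem(x)
        c2 = self.stage2(self.stage1(x))
        c3 = self.stage3(c2)
        c4 = self.stage4(c3)
        feats = [self.lateral3(c2), self.lateral4(c3), self.lateral5(c4)]
        for layer in self.bifpn:
            feats = layer(feats)
        feats = [self.out3(feats[0]), self.out4(feats[1]), self.out5(feats[2])]
        return [head(f) for head, f in zip(self.heads, feats)]


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Instantiate and deterministically initialize the detector."""
    model = Detector(cfg)
    nn.init_weights(model, seed=seed)
    # bias the classification logits toward background so early training
    # is not swamped by false positives
    prior = -float(np.log((1 - 0.01) / 0.01))
    for head in model.heads:
        head.cls.mods[-1].bias.data[:] = prior
    return model


# ---------------------------------------------------------------------
# decoding and suppression
# ---------------------------------------------------------------------

def _sigmoid(z):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def decode_level(reg: np.ndarray, cls: np.ndarray, stride: int, regmax: int):
    """Decode one level's raw maps (channel-first, no batch axis) into
    per-cell boxes, scores and classes in pixel units."""
    _, h, w = cls.shape
    dist_logits = reg.reshape(4, regmax, h, w)
    prob = np.exp(dist_logits - dist_logits.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    bins = np.arange(regmax, dtype=float).reshape(1, regmax, 1, 1)
    dist = (prob * bins).sum(axis=1) * stride          # (4, h, w): l, t, r, b
    cx = (np.arange(w, dtype=float) + 0.5)[None, :] * stride
    cy = (np.arange(h, dtype=float) + 0.5)[:, None] * stride
    boxes = np.stack([
        cx - dist[0], cy - dist[1], cx + dist[2], cy + dist[3],
    ], axis=0)                                          # (4, h, w)
    scores = _sigmoid(cls)
    class_id = scores.argmax(axis=0)
    conf = scores.max(axis=0)
    return boxes.reshape(4, -1).T, conf.reshape(-1), class_id.reshape(-1)


def decode_predictions(raw, cfg: ModelConfig, conf_threshold: float = 0.25,
                       img_size: int | tuple = 640) -> list:
    """Turn raw per-level prediction maps into Detections.

    `raw` is the Detector.forward output for a single image (batch axis
    absent or of size 1). Boxes are clipped to the image.
    """
    if isinstance(img_size, int):
        img_w = img_h = img_size
    else:
        img_h, img_w = img_size
    dets = []
    for (reg, cls), stride in zip(raw, cfg.strides):
        reg_d = reg.data if isinstance(reg, nn.Tensor) else np.asarray(reg)
        cls_d = cls.data if isinstance(cls, nn.Tensor) else np.asarray(cls)
        if reg_d.ndim == 4:
            if reg_d.shape[0] != 1:
                raise ValueError("decode_predictions expects a single image")
            reg_d, cls_d = reg_d[0], cls_d[0]
        boxes, conf, class_id = decode_level(reg_d, cls_d, stride, cfg.regmax)
        keep = conf >= conf_threshold
        for b, s, c in zip(boxes[keep], conf[keep], class_id[keep]):
            x1 = float(np.clip(b[0], 0, img_w))
            y1 = float(np.clip(b[1], 0, img_h))
            x2 = float(np.clip(b[2], 0, img_w))
            y2 = float(np.clip(b[3], 0, img_h))
            if x2 <= x1 or y2 <= y1:
                continue
            dets.append(Detection(box=(x1, y1, x2, y2), score=float(s),
                                  class_id=int(c)))
    return dets


def nms(dets, iou_threshold: float = 0.45) -> list:
    """Greedy class-wise non-maximum suppression; ties broken by score
    then original index (stable)."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(dets[i])
        for j in order:
            if j == i or j in suppressed:
                continue
            if dets[j].class_id != dets[i].class_id:
                continue
            if iou_matrix([dets[i].box], [dets[j].box])[0, 0] > iou_threshold:
                suppressed.add(j)
    return kept


def predict(model: Detector, image_chw: np.ndarray, conf_threshold: float = 0.25,
            iou_threshold: float = 0.45) -> list:
    """Forward one (3,H,W) float image in eval mode, decode and suppress."""
    was_training = model.training
    model.eval()
    try:
        raw = model(nn.Tensor(image_chw[None].astype(np.float32)))
    finally:
        model.train(was_training)
    h, w = image_chw.shape[1], image_chw.shape[2]
    dets = decode_predictions(raw, model.cfg, conf_threshold, (h, w))
    return nms(dets, iou_threshold)


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(path, model: Detector, seed: int = 0, epoch: int = 0,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: versioned header + config + weights."""
    header = {
        "magic": CHECKPOINT_MAGIC,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(model.cfg).items()},
        "seed": seed,
        "epoch": epoch,
        "extra": extra or {},
    }
    arrays = model.state_dict()
    buf = io.BytesIO()
    np.savez(buf, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> tuple[Detector, dict]:
    data = np.load(Path(path), allow_pickle=False)
    header = json.loads(bytes(data["__header__"]).decode())
    if header.get("magic") != CHECKPOINT_MAGIC:
        raise ValueError(f"{path} is not a {CHECKPOINT_MAGIC} checkpoint")
    cfg_d = header["config"]
    for k, v in cfg_d.items():
        if isinstance(v, list):
            cfg_d[k] = tuple(v)
    cfg = ModelConfig(**cfg_d)
    model = Detector(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    return model, header
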