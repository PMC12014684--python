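"""Detection evaluation: IoU, greedy score-ordered matching, precision /
recall, 101-point interpolated average precision, and the mAP50 /
mAP50-95 suite.

Matching convention: detections are processed in descending score order
and each is matched to the unmatched ground truth of highest IoU >= the
threshold; a ground truth is matched at most once. AP uses COCO-style
101-point interpolation. Reported P and R are taken at the confidence
that maximizes F1 along the ranked detection list. 0/0 ratios are 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection",
    "GroundTruthBox",
    "MatchResult",
    "MetricsReport",
    "iou",
    "iou_matrix",
    "match_detections",
    "precision_recall",
    "average_precision",
    "map_suite",
    "MAP_THRESHOLDS",
]

# IoU thresholds 0.50 + 0.05*(j-1), j = 1..10
MAP_THRESHOLDS = tuple(round(0.5 + 0.05 * j, 2) for j in range(10))


@dataclass(frozen=True)
class Detection:
    """Predicted box in pixel xyxy (half-open, 0-based) with score and class."""

    box: tuple  # (x1, y1, x2, y2)
    score: float
    class_id: int = 0


@dataclass(frozen=True)
class GroundTruthBox:
    box: tuple
    class_id: int = 0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    # True/False per detection, ordered by descending score
    flags: list = field(default_factory=list)


def _box_area(b) -> float:
    return max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])


def iou(a, b) -> float:
    """Intersection-over-union of two xyxy boxes; 0 for disjoint or
    degenerate zero-area boxes."""
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    union = _box_area(a) + _box_area(b) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (Na,4) and (Nb,4) xyxy arrays."""
    a = np.asarray(boxes_a, float).reshape(-1, 4)
    b = np.asarray(boxes_b, float).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def match_detections(dets, gts, iou_threshold: float) -> MatchResult:
    """Greedy single-class matching (callers loop over classes)."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(gts)
    flags = []
    for i in order:
        best_j, best_v = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(dets[i].box, gt.box)
            if v >= iou_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return MatchResult(tp=tp, fp=len(flags) - tp, fn=len(gts) - tp, flags=flags)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    return p, r


def _ap_from_flags(flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from score-ordered TP flags."""
    if n_gt == 0:
        raise ValueError("AP undefined with no ground truths")
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, monotone non-increasing from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    rec_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, rec_points, side="left")
    sampled = np.where(idx < recall.size, prec_env[np.minimum(idx, recall.size - 1)], 0.0)
    return float(sampled.mean())


def average_precision(dets, gts, iou_threshold: float) -> float:
    """AP of one class at one IoU threshold."""
    if len(gts) == 0:
        raise ValueError("AP undefined for a class with no ground truths")
    m = match_detections(dets, gts, iou_threshold)
    return _ap_from_flags(np.asarray(m.flags, bool), len(gts))


@dataclass
class MetricsReport:
    precision: float
    recall: float
    # per_class_ap[class_id] = list of AP over MAP_THRESHOLDS
    per_class_ap: dict
    map50: float
    map50_95: float

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "map50": self.map50,
            "map50_95": self.map50_95,
            "per_class_ap": {
                int(c): [float(v) for v in aps]
                for c, aps in self.per_class_ap.items()
            },
        }


def _best_f1_operating_point(dets, gts, iou_threshold=0.5):
    """P and R at the score cut that maximizes F1 (over all classes pooled)."""
    n_gt = len(gts)
    flags, scores = [], []
    by_class = {}
    for gt in gts:
        by_class.setdefault(gt.class_id, ([], []))[1].append(gt)
    for d in dets:
        by_class.setdefault(d.class_id, ([], []))[0].append(d)
    for c, (cdets, cgts) in by_class.items():
        m = match_detections(cdets, cgts, iou_threshold)
        order = sorted(cdets, key=lambda d: -d.score)
        flags.extend(m.flags)
        scores.extend(d.score for d in order)
    if not flags:
        return 0.0, 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    f = np.asarray(flags, bool)[order]
    tp = np.cumsum(f)
    fp = np.cumsum(~f)
    p = tp / (tp + fp)
    r = tp / n_gt if n_gt else np.zeros_like(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where((p + r) > 0, 2 * p * r / (p + r), 0.0)
    k = int(np.argmax(f1))
    return float(p[k]), float(r[k])


def map_suite(dets, gts) -> MetricsReport:
    """Full report: per-class AP at each threshold, mAP50, mAP50-95, and
    P/R at the best-F1 operating point. Classes with no ground truths are
    excluded from the means with a warning."""
    if len(gts) == 0:
        raise ValueError("empty evaluation set: no ground-truth boxes")
    classes = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    per_class_ap = {}
    for c in classes:
        cgts = [g for g in gts if g.class_id == c]
        cdets = [d for d in dets if d.class_id == c]
        if not cgts:
            warnings.warn(f"class {c} has detections but no ground truths; "
                          "excluded from mAP", stacklevel=2)
            continue
        per_class_ap[c] = [average_precision(cdets, cgts, t) for t in MAP_THRESHOLDS]
    ap50 = [aps[0] for aps in per_class_ap.values()]
    ap_all = [float(np.mean(aps)) for aps in per_class_ap.values()]
    p, r = _best_f1_operating_point(dets, gts)
    return MetricsReport(
        precision=p,
        recall=r,
        per_class_ap=per_class_ap,
        map50=float(np.mean(ap50)),
        map50_95=float(np.mean(ap_all)),
    )
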