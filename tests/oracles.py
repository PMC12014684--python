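"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested loops, exhaustive
enumeration, shapely geometry) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import box as shapely_box


def conv2d_oracle(x, w, stride=1, padding=0, groups=1, bias=None,
                  count_macs=False):
    """Nested-loop direct convolution on a (C,H,W) input.

    Returns the output array, or (output, mac_count) when `count_macs`.
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    c, h, wd = x.shape
    cout, cg, k, _ = w.shape
    assert c % groups == 0 and cout % groups == 0 and cg == c // groups
    p, s = padding, stride
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    out = np.zeros((cout, ho, wo))
    macs = 0
    for oc in range(cout):
        g = oc // (cout // groups)
        for oy in range(ho):
            for ox in range(wo):
                acc = 0.0
                for ic in range(cg):
                    for ky in range(k):
                        for kx in range(k):
                            acc += (xp[g * cg + ic, oy * s + ky, ox * s + kx]
                                    * w[oc, ic, ky, kx])
                            macs += 1
                out[oc, oy, ox] = acc
    if bias is not None:
        out += np.asarray(bias, float)[:, None, None]
    return (out, macs) if count_macs else out


def iou_oracle(a, b) -> float:
    """IoU via shapely polygon areas."""
    pa = shapely_box(a[0], a[1], a[2], a[3])
    pb = shapely_box(b[0], b[1], b[2], b[3])
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def greedy_match_oracle(det_boxes, det_scores, gt_boxes, thr):
    """Greedy matcher re-derived from the stated convention; returns the
    TP flag list in descending-score order."""
    order = sorted(range(len(det_boxes)), key=lambda i: -det_scores[i])
    taken = set()
    flags = []
    for i in order:
        best, best_v = None, 0.0
        for j in range(len(gt_boxes)):
            if j in taken:
                continue
            v = iou_oracle(det_boxes[i], gt_boxes[j])
            if v >= thr and v > best_v:
                best, best_v = j, v
        if best is not None:
            taken.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def ap_oracle(flags, n_gt) -> float:
    """101-point AP straight from its definition: for each recall sample,
    the best precision among ranking prefixes reaching that recall."""
    assert n_gt > 0
    prefixes = []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + bool(f), fp + (not f)
        prefixes.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for i in range(101):
        rp = i / 100.0
        cands = [p for r, p in prefixes if r >= rp - 1e-12]
        total += max(cands) if cands else 0.0
    return total / 101.0


def nms_oracle(boxes, scores, classes, thr):
    """Greedy NMS re-derived from the definition; returns kept indices."""
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        if any(classes[i] == classes[j]
               and iou_oracle(boxes[i], boxes[j]) > thr for j in kept):
            continue
        kept.append(i)
    return kept
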