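"""Detection metrics: precision/recall, greedy IoU matching, P-R curves,
per-class average precision and mAP.

The protocol is the familiar VOC-style one: detections are ranked by score;
each detection is a true positive if it overlaps an unmatched same-class
ground-truth box with IoU at or above the threshold (each ground truth can
absorb at most one detection); precision = TP/(TP+FP) and recall =
TP/(TP+FN) are swept over the ranking; AP is the area under the
monotone-envelope precision-recall curve, and mAP averages AP over classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import DetBox, GTBox, box_iou

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "precision",
    "recall",
    "match",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); undefined when no detections were made."""
    if c.tp + c.fp == 0:
        raise ValueError("precision undefined: no detections (TP + FP = 0)")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); undefined when there is no ground truth."""
    if c.tp + c.fn == 0:
        raise ValueError("recall undefined: no ground truth (TP + FN = 0)")
    return c.tp / (c.tp + c.fn)


def match(
    dets: list[DetBox],
    gts: list[GTBox],
    iou_thresh: float = 0.5,
) -> list[bool]:
    """Greedy per-image matching; returns a TP flag per detection.

    Detections are visited in descending score order (deterministic
    tie-breaks as in NMS); each matches the highest-IoU not-yet-matched
    ground truth of its own class with IoU >= ``iou_thresh``.  The returned
    flags are aligned with the score-sorted detection order that
    :func:`sort_detections` produces.
    """
    order = sort_detections(dets)
    taken = [False] * len(gts)
    flags: list[bool] = []
    for d in order:
        best, best_iou = -1, iou_thresh
        for j, gt in enumerate(gts):
            if taken[j] or gt.class_id != d.class_id:
                continue
            iou = box_iou(d, gt)
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            taken[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def sort_detections(dets: list[DetBox]) -> list[DetBox]:
    return sorted(dets, key=lambda d: (-d.score, -d.area, d.x1))


def pr_curve(labels: list[bool], n_gt: int) -> list[tuple[float, float]]:
    """(recall, precision) after each detection in rank order."""
    if n_gt == 0:
        raise ValueError("P-R curve undefined with no ground truth")
    pts = []
    tp = fp = 0
    for is_tp in labels:
        tp += is_tp
        fp += not is_tp
        pts.append((tp / n_gt, tp / (tp + fp)))
    return pts


def average_precision(
    pr_points: list[tuple[float, float]],
    interpolation: str = "all_points",
) -> float:
    """Area under the P-R curve.

    ``all_points``: make the precision envelope monotone non-increasing in
    recall and sum it over recall increments.  ``eleven_point``: mean of the
    interpolated precision at recalls 0, 0.1, ..., 1.
    """
    if not pr_points:
        return 0.0
    rec = np.array([r for r, _ in pr_points])
    prec = np.array([p for _, p in pr_points])
    if interpolation == "eleven_point":
        ap = 0.0
        for t in np.linspace(0, 1, 11):
            mask = rec >= t - 1e-12
            ap += prec[mask].max() if mask.any() else 0.0
        return ap / 11
    if interpolation != "all_points":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    r = np.concatenate([[0.0], rec, [rec[-1]]])
    p = np.concatenate([[0.0], prec, [0.0]])
    # monotone non-increasing precision envelope
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_ap(per_class_aps: dict[int, float] | list[float]) -> float:
    """Arithmetic mean of per-class APs."""
    vals = list(per_class_aps.values()) if isinstance(per_class_aps, dict) else list(per_class_aps)
    if not vals:
        raise ValueError("at least one class required")
    return float(np.mean(vals))


@dataclass
class EvalResult:
    per_class_ap: dict[int, float]
    map: float
    pr_points: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


def evaluate_detections(
    preds: list[list[DetBox]],
    gts: list[list[GTBox]],
    iou_thresh: float = 0.5,
    num_classes: int = 2,
    interpolation: str = "all_points",
) -> EvalResult:
    """Dataset-level per-class AP and mAP over parallel per-image lists.

    Classes with no ground truth anywhere are excluded from the mean.
    """
    if len(preds) != len(gts):
        raise ValueError("preds and gts must be parallel per-image lists")
    per_class_ap: dict[int, float] = {}
    pr: dict[int, list[tuple[float, float]]] = {}
    for c in range(num_classes):
        n_gt = sum(1 for gl in gts for g in gl if g.class_id == c)
        if n_gt == 0:
            continue
        scored: list[tuple[float, float, float, bool]] = []
        for dl, gl in zip(preds, gts):
            dc = [d for d in dl if d.class_id == c]
            gc = [g for g in gl if g.class_id == c]
            flags = match(dc, gc, iou_thresh)
            for d, f in zip(sort_detections(dc), flags):
                scored.append((-d.score, -d.area, d.x1, f))
        scored.sort()
        labels = [f for *_, f in scored]
        points = pr_curve(labels, n_gt) if labels else []
        per_class_ap[c] = average_precision(points, interpolation)
        pr[c] = points
    if not per_class_ap:
        raise ValueError("no ground truth in any class")
    return EvalResult(per_class_ap=per_class_ap, map=mean_ap(per_class_ap), pr_points=pr)
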