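"""Object-detection metrics: IoU matching, precision/recall/F1, score sweeps.

A prediction matches a ground-truth box when their intersection-over-union
reaches the IoU threshold (0.5 by default).  Matching is one-to-one and
greedy in descending score order — the community (VOC/COCO-style)
convention: each prediction consumes the unmatched truth of highest IoU or
becomes a false positive; unmatched truths are false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatchCounts",
    "MetricRow",
    "iou",
    "match_detections",
    "prf_metrics",
    "threshold_sweep",
    "round_half_up",
]

DEFAULT_IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class MatchCounts:
    """TP/FP/FN tallies; TP+FP = detections, TP+FN = targets."""

    tp: int
    fp: int
    fn: int

    @property
    def detections(self) -> int:
        return self.tp + self.fp

    @property
    def targets(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricRow:
    score_threshold: float
    counts: MatchCounts
    precision: float
    recall: float
    f1: float


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x_min, y_min, x_max, y_max) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError("degenerate box")
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def match_detections(preds, truths, iou_threshold: float = DEFAULT_IOU_THRESHOLD
                     ) -> MatchCounts:
    """Greedy one-to-one matching of scored predictions to ground truths.

    ``preds``: sequence of ``(box, score)``; ``truths``: sequence of boxes.
    Predictions are visited in descending score order; each takes the
    still-unmatched truth of highest IoU if that IoU >= threshold (ties
    broken by truth index).
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    matched = [False] * len(truths)
    tp = 0
    for i in order:
        box = preds[i][0]
        best_j, best_iou = -1, 0.0
        for j, truth in enumerate(truths):
            if matched[j]:
                continue
            v = iou(box, truth)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp += 1
    return MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp)


def prf_metrics(c: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts; 0 on empty denominators."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal rounding with ties away from zero, for report formatting."""
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def threshold_sweep(preds, truths, thresholds,
                    iou_threshold: float = DEFAULT_IOU_THRESHOLD) -> list[MetricRow]:
    """Score-threshold sweep: filter predictions, match, report per threshold."""
    rows = []
    for thr in thresholds:
        kept = [p for p in preds if p[1] >= thr]
        counts = match_detections(kept, truths, iou_threshold)
        p, r, f1 = prf_metrics(counts)
        rows.append(MetricRow(score_threshold=thr, counts=counts,
                              precision=p, recall=r, f1=f1))
    return rows


def sweep_to_frame(rows: list[MetricRow]) -> pd.DataFrame:
    """Tabulate a sweep with 3-decimal half-up metric rounding."""
    return pd.DataFrame([
        {
            "threshold": r.score_threshold,
            "targets": r.counts.targets,
            "detections": r.counts.detections,
            "TP": r.counts.tp,
            "FP": r.counts.fp,
            "FN": r.counts.fn,
            "precision": round_half_up(r.precision),
            "recall": round_half_up(r.recall),
            "f1": round_half_up(r.f1),
        }
        for r in rows
    ])
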