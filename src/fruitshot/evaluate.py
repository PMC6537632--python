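"""Detection evaluation: confusion counts, precision/recall/F1, mean IoU.

Matching follows the VOC protocol: detections are visited in descending
confidence; each claims the unmatched ground truth of highest IoU,
provided that IoU reaches the threshold (0.5 by convention here — below
that a detection counts as poor).  Counts are pooled over the whole
dataset before ratios are computed (micro-averaging, i.e. one confusion
matrix for the dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .boxes import Box, iou
from .tiler import DetectionSet

__all__ = ["MatchResult", "EvalReport", "match", "report"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_ious: list[float] = field(default_factory=list)


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    mean_iou: float
    per_image: list[MatchResult] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_iou": self.mean_iou,
        }


def match(
    detections: DetectionSet | Sequence[Box],
    truths: Sequence[Box],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of one image's detections to its truths."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    boxes = detections.boxes if isinstance(detections, DetectionSet) else list(detections)
    order = sorted(boxes, key=lambda b: -(b.confidence if b.confidence is not None else 1.0))
    unmatched = list(truths)
    tp = 0
    ious: list[float] = []
    for det in order:
        best_i, best_v = -1, 0.0
        for i, t in enumerate(unmatched):
            v = iou(det, t)
            if v > best_v:
                best_i, best_v = i, v
        if best_i >= 0 and best_v >= iou_threshold:
            unmatched.pop(best_i)
            tp += 1
            ious.append(best_v)
    return MatchResult(tp=tp, fp=len(boxes) - tp, fn=len(unmatched), matched_ious=ious)


def report(matches: Sequence[MatchResult], strict_iou: bool = False) -> EvalReport:
    """Aggregate per-image matches into one pooled report.

    ``mean_iou`` averages over matched pairs; with ``strict_iou`` every
    unmatched detection or truth also contributes a zero, which penalizes
    misses in the IoU figure as well.
    """
    tp = sum(m.tp for m in matches)
    fp = sum(m.fp for m in matches)
    fn = sum(m.fn for m in matches)
    if tp + fp + fn == 0:
        raise ValueError("nothing to evaluate: no detections and no truths")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    all_ious = [v for m in matches for v in m.matched_ious]
    denom = len(all_ious) + (fp + fn if strict_iou else 0)
    mean_iou = sum(all_ious) / denom if denom else 0.0
    return EvalReport(tp, fp, fn, precision, recall, f1, mean_iou, per_image=list(matches))
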