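"""Bounding-box geometry, IoU, anchor priors and grid-cell box decoding.

All coordinates in this package are 0-based, half-open pixel intervals:
a box covers ``[x_min, x_max) x [y_min, y_max)``.  Format-specific corner
conventions (VOC's 1-based inclusive corners, DARKNET's normalized centers)
are handled exclusively in :mod:`fruitshot.labels_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "RawPrediction",
    "AnchorSet",
    "iou",
    "decode",
    "nms",
    "fit_anchors",
]


@dataclass(frozen=True)
class Box:
    """One axis-aligned bounding box with a class label and optional confidence.

    Invariants: ``x_min < x_max`` and ``y_min < y_max`` (strictly positive
    area).  ``confidence`` is ``None`` for ground truth.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: int = 0
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) has non-positive area"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translated(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def clipped(self, width: float, height: float) -> "Box | None":
        """Clip to the frame ``[0, width) x [0, height)``; None if nothing is left."""
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, float(width))
        y1 = min(self.y_max, float(height))
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)


@dataclass(frozen=True)
class RawPrediction:
    """Raw network outputs for one anchor slot of one grid cell.

    ``t_x, t_y, t_w, t_h`` and ``objectness`` are unbounded reals; the grid
    cell indices ``(grid_col, grid_row)`` locate the cell and
    ``anchor_index`` selects the prior.  ``class_scores`` holds the
    per-class outputs (length 1 for the single-class fruit models).
    """

    t_x: float
    t_y: float
    t_w: float
    t_h: float
    objectness: float
    grid_col: int
    grid_row: int
    anchor_index: int
    class_scores: tuple[float, ...] = (0.0,)


@dataclass(frozen=True)
class AnchorSet:
    """Anchor-box priors: (width, height) pairs in grid-cell units.

    Five priors per cell is the default; sizes span 0.5-8 cells so that
    near-uniform fruit sizes always have a nearby prior.
    """

    priors: tuple[tuple[float, float], ...] = (
        (0.5, 0.5),
        (1.0, 1.0),
        (2.0, 2.0),
        (4.0, 4.0),
        (8.0, 8.0),
    )

    def __post_init__(self) -> None:
        if len(self.priors) < 1:
            raise ValueError("at least one anchor prior is required")
        for w, h in self.priors:
            if w <= 0 or h <= 0:
                raise ValueError(f"anchor prior ({w}, {h}) must be strictly positive")

    def __len__(self) -> int:
        return len(self.priors)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def decode(
    raw: RawPrediction,
    anchors: AnchorSet,
    grid_size: int,
    image_size: int,
) -> Box:
    """Decode one raw grid prediction into a pixel-space box.

    The center is ``(sigmoid(t_x) + grid_col, sigmoid(t_y) + grid_row)`` in
    cell units — always inside its source cell — and the size is the anchor
    prior scaled by ``exp(t_w), exp(t_h)``.  Cell units convert to pixels by
    ``image_size / grid_size`` (a real number; the grid need not divide the
    image evenly).  Confidence is ``sigmoid(objectness)`` times the largest
    sigmoid class score.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    if not (0 <= raw.grid_col < grid_size and 0 <= raw.grid_row < grid_size):
        raise ValueError("grid cell indices outside the grid")
    if not (0 <= raw.anchor_index < len(anchors)):
        raise ValueError("anchor_index outside anchor set")

    cell = image_size / grid_size
    cx = (_sigmoid(raw.t_x) + raw.grid_col) * cell
    cy = (_sigmoid(raw.t_y) + raw.grid_row) * cell
    pw, ph = anchors.priors[raw.anchor_index]
    w = pw * math.exp(raw.t_w) * cell
    h = ph * math.exp(raw.t_h) * cell
    conf = _sigmoid(raw.objectness) * max(_sigmoid(s) for s in raw.class_scores)
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, label=0, confidence=conf)


def nms(detections: Sequence[Box], iou_threshold: float = 0.45) -> list[Box]:
    """Greedy non-maximum suppression in descending confidence order.

    A box is dropped when its IoU with an already-kept box exceeds
    ``iou_threshold``.  Output is sorted by confidence, and is always a
    subset of the input (idempotent).
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside [0, 1]")
    for d in detections:
        if d.confidence is None:
            raise ValueError("nms requires a confidence on every box")
    kept: list[Box] = []
    for cand in sorted(detections, key=lambda b: -b.confidence):  # type: ignore[operator]
        if all(iou(cand, k) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def fit_anchors(
    boxes: Iterable[Box],
    n_anchors: int,
    cell_size: float,
    n_iter: int = 50,
    seed: int = 0,
) -> AnchorSet:
    """Fit anchor priors to labeled box sizes with k-means in (w, h) cell units.

    Uses the conventional 1 - IoU distance between a box size and a prior
    (both centered at the origin), which favors priors matching both scale
    and aspect ratio.
    """
    sizes = np.array([[b.width / cell_size, b.height / cell_size] for b in boxes])
    if len(sizes) < n_anchors:
        raise ValueError("need at least as many boxes as anchors")
    rng = np.random.default_rng(seed)
    centers = sizes[rng.choice(len(sizes), n_anchors, replace=False)]

    def dist(sz: np.ndarray, ct: np.ndarray) -> np.ndarray:
        inter = np.minimum(sz[:, None, 0], ct[None, :, 0]) * np.minimum(
            sz[:, None, 1], ct[None, :, 1]
        )
        union = sz[:, None, 0] * sz[:, None, 1] + ct[None, :, 0] * ct[None, :, 1] - inter
        return 1.0 - inter / union

    for _ in range(n_iter):
        assign = dist(sizes, centers).argmin(axis=1)
        new = np.array(
            [
                sizes[assign == k].mean(axis=0) if np.any(assign == k) else centers[k]
                for k in range(n_anchors)
            ]
        )
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return AnchorSet(tuple((float(w), float(h)) for w, h in centers[order]))
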