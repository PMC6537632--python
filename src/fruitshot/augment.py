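"""Label-aware data augmentation: k seeded random variants per image.

Geometric operations (flip, scale, rotate, perspective) move the boxes by
the same map as the pixels, replacing rotated boxes by their axis-aligned
hull; photometric operations (color jitter, contrast, noise) leave boxes
untouched.  The output canvas always keeps the input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf

from .boxes import Box
from .labels_io import AnnotatedImage, clip_boxes

__all__ = ["AugmentOp", "KINDS", "apply", "augment_dataset"]

KINDS = ("hflip", "scale", "rotate", "color_jitter", "contrast", "noise", "perspective")

# Default parameter ranges: mild, label-preserving perturbations.
DEFAULT_PARAMS: dict[str, dict] = {
    "hflip": {},
    "scale": {"range": (0.7, 1.3)},
    "rotate": {"degrees": (-15.0, 15.0)},
    "color_jitter": {"shift": (-30, 30)},
    "contrast": {"factor": (0.7, 1.3)},
    "noise": {"sigma": (2.0, 12.0)},
    "perspective": {"jitter_frac": 0.05},
}


@dataclass(frozen=True)
class AugmentOp:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}")

    def resolved(self) -> dict:
        merged = dict(DEFAULT_PARAMS[self.kind])
        merged.update(self.params)
        return merged


def _warp_boxes(boxes: list[Box], matrix: np.ndarray) -> list[Box]:
    """Map box corners through a 3x3 homogeneous matrix; take the AA hull."""
    out = []
    for b in boxes:
        corners = np.array(
            [
                [b.x_min, b.y_min, 1.0],
                [b.x_max, b.y_min, 1.0],
                [b.x_min, b.y_max, 1.0],
                [b.x_max, b.y_max, 1.0],
            ]
        )
        warped = corners @ matrix.T
        warped = warped[:, :2] / warped[:, 2:3]
        x0, y0 = warped.min(axis=0)
        x1, y1 = warped.max(axis=0)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            continue
        out.append(Box(x0, y0, x1, y1, label=b.label, confidence=b.confidence))
    return out


def _check_frame_visible(matrix: np.ndarray, W: int, H: int, kind: str) -> None:
    """Reject a transform whose mapped frame misses the canvas entirely.

    Centered scale/rotate can never trigger this; the guard protects
    transforms supplied with explicit matrices (e.g. strong perspectives
    or translations added by callers).
    """
    frame = np.array([[0, 0, 1], [W, 0, 1], [W, H, 1], [0, H, 1]], dtype=float)
    mapped = frame @ matrix.T
    mapped = mapped[:, :2] / mapped[:, 2:3]
    if (
        mapped[:, 0].max() <= 0
        or mapped[:, 0].min() >= W
        or mapped[:, 1].max() <= 0
        or mapped[:, 1].min() >= H
    ):
        raise ValueError(f"{kind} maps the whole image out of frame")


def _warp_image(img: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    # skimage warps with the inverse map, pixel-out <- pixel-in.
    tf = sktf.ProjectiveTransform(matrix=matrix)
    warped = sktf.warp(img.astype(np.float64) / 255.0, tf.inverse, order=1, mode="constant", cval=0.0)
    return np.clip(warped * 255.0, 0, 255).astype(np.uint8)


def apply(a: AnnotatedImage, op: AugmentOp, seed: int = 0) -> AnnotatedImage:
    """Apply one augmentation; deterministic for a fixed (op, seed)."""
    rng = np.random.default_rng(seed)
    p = op.resolved()
    H, W = a.height, a.width
    img = a.image
    boxes = list(a.boxes)

    if op.kind == "hflip":
        img = img[:, ::-1].copy()
        boxes = [
            Box(W - b.x_max, b.y_min, W - b.x_min, b.y_max, b.label, b.confidence)
            for b in boxes
        ]
    elif op.kind in ("scale", "rotate", "perspective"):
        if op.kind == "scale":
            s = rng.uniform(*p["range"])
            cx, cy = W / 2, H / 2
            matrix = np.array(
                [[s, 0, cx - s * cx], [0, s, cy - s * cy], [0, 0, 1]], dtype=float
            )
        elif op.kind == "rotate":
            deg = rng.uniform(*p["degrees"])
            th = math.radians(deg)
            cx, cy = W / 2, H / 2
            c, s = math.cos(th), math.sin(th)
            matrix = np.array(
                [
                    [c, -s, cx - c * cx + s * cy],
                    [s, c, cy - s * cx - c * cy],
                    [0, 0, 1],
                ]
            )
        else:  # perspective: jitter the four corners and fit a homography
            j = p["jitter_frac"]
            src = np.array([[0, 0], [W, 0], [W, H], [0, H]], dtype=float)
            dst = src + rng.uniform(-j, j, size=(4, 2)) * [W, H]
            if hasattr(sktf.ProjectiveTransform, "from_estimate"):
                tf = sktf.ProjectiveTransform.from_estimate(src, dst)
                if not tf:
                    raise ValueError("degenerate perspective transform")
            else:  # older scikit-image
                tf = sktf.ProjectiveTransform()
                if not tf.estimate(src, dst):
                    raise ValueError("degenerate perspective transform")
            matrix = tf.params
        _check_frame_visible(matrix, W, H, op.kind)
        img = _warp_image(img, matrix)
        boxes = clip_boxes(_warp_boxes(boxes, matrix), W, H)
    elif op.kind == "color_jitter":
        shift = rng.integers(p["shift"][0], p["shift"][1] + 1, size=3)
        img = np.clip(img.astype(np.int16) + shift[None, None, :], 0, 255).astype(np.uint8)
    elif op.kind == "contrast":
        f = rng.uniform(*p["factor"])
        mean = img.mean(axis=(0, 1), keepdims=True)
        img = np.clip((img - mean) * f + mean, 0, 255).astype(np.uint8)
    elif op.kind == "noise":
        sigma = rng.uniform(*p["sigma"])
        noisy = img.astype(np.float64) + rng.normal(0, sigma, img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8)

    return AnnotatedImage(img, boxes, source_id=f"{a.source_id}+{op.kind}")


def augment_dataset(
    images: list[AnnotatedImage],
    k: int = 3,
    seed: int = 0,
    kinds: tuple[str, ...] = KINDS,
) -> list[AnnotatedImage]:
    """For each input produce k variants with uniformly drawn op kinds.

    Output order is input-major (all variants of image 0, then image 1, ...)
    and the drawn op sequence is a pure function of the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not images:
        raise ValueError("empty input list")
    rng = np.random.default_rng(seed)
    out: list[AnnotatedImage] = []
    for a in images:
        for j in range(k):
            kind = kinds[int(rng.integers(len(kinds)))]
            op_seed = int(rng.integers(2**31))
            variant = apply(a, AugmentOp(kind), seed=op_seed)
            variant.source_id = f"{a.source_id}+aug{j}_{kind}"
            out.append(variant)
    return out
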