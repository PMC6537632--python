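"""Splitter/joiner tiling for high-resolution frames.

Small fruits shrink below detectability when a large frame is resized to
the detector's input; instead the frame is split into detector-sized
tiles (the canonical case: one 1216 x 1216 frame into exactly four
608 x 608 tiles), each tile is detected independently, and the per-tile
detections are re-projected into frame coordinates.  Fruits cut by a
tile seam can be detected twice — once per adjacent tile — so the joiner
runs a cross-tile merge restricted to boxes near seams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .boxes import Box, iou, nms

__all__ = ["TileSet", "DetectionSet", "split", "join", "detect_tiled"]

SEAM_MARGIN_DEFAULT = 4.0  # px: how close to a tile border a box must be to join seam merging
SEAM_MERGE_IOU = 0.3  # IoU above which two seam boxes are considered the same fruit


@dataclass
class DetectionSet:
    """Decoded, thresholded detections for one frame, in frame pixels."""

    boxes: list[Box] = field(default_factory=list)
    frame_size: tuple[int, int] = (0, 0)  # (W, H)

    def __post_init__(self) -> None:
        W, H = self.frame_size
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > W or b.y_max > H:
                raise ValueError(f"box {b} outside frame {self.frame_size}")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class TileSet:
    """A partition of a source frame into equally sized square tiles."""

    tiles: tuple[tuple[np.ndarray, int, int], ...]  # (image, origin_x, origin_y)
    grid: tuple[int, int]  # (rows, cols)
    source_size: tuple[int, int]  # (W, H)
    tile_size: int = 608
    padding: tuple[int, int] = (0, 0)  # (right, bottom) zero padding applied


def split(image: np.ndarray, tile_size: int = 608) -> TileSet:
    """Partition an H x W x 3 image into row-major square tiles.

    Dimensions not divisible by the tile size are zero-padded on the
    right/bottom edges and the padding is recorded.  Reassembling tile
    pixels reproduces the (padded) source exactly — tiles never overlap
    and never leave gaps.
    """
    H, W = image.shape[:2]
    if tile_size > H or tile_size > W:
        raise ValueError(f"tile_size {tile_size} exceeds image {W}x{H}")
    pad_r = (-W) % tile_size
    pad_b = (-H) % tile_size
    if pad_r or pad_b:
        image = np.pad(image, ((0, pad_b), (0, pad_r), (0, 0)))
    rows = image.shape[0] // tile_size
    cols = image.shape[1] // tile_size
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * tile_size, c * tile_size
            tiles.append((image[y0 : y0 + tile_size, x0 : x0 + tile_size], x0, y0))
    return TileSet(tuple(tiles), (rows, cols), (W, H), tile_size, (pad_r, pad_b))


def _near_seam(b: Box, tileset: TileSet, origin: tuple[int, int], margin: float) -> bool:
    """Is the box within `margin` px of an interior tile border?"""
    ts = tileset.tile_size
    rows, cols = tileset.grid
    ox, oy = origin
    col, row = ox // ts, oy // ts
    return (
        (col > 0 and b.x_min <= margin)
        or (col < cols - 1 and b.x_max >= ts - margin)
        or (row > 0 and b.y_min <= margin)
        or (row < rows - 1 and b.y_max >= ts - margin)
    )


def _union_box(a: Box, b: Box) -> Box:
    return Box(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
        label=a.label,
        confidence=max(a.confidence or 0.0, b.confidence or 0.0),
    )


def _extended(b: Box, tileset: TileSet, origin: tuple[int, int], margin: float) -> Box:
    """Mirror-extend a box across every interior tile border it touches.

    A fruit cut by a seam shows up as two half-boxes that abut but barely
    overlap; extending each half across the seam by its own extent (a
    mirror of the visible half) makes the two extensions coincide, so an
    IoU test can recognize them as one object.  Box and origin are in
    tile coordinates; the result is in frame coordinates.
    """
    ts = tileset.tile_size
    rows, cols = tileset.grid
    ox, oy = origin
    col, row = ox // ts, oy // ts
    x0, y0, x1, y1 = b.x_min, b.y_min, b.x_max, b.y_max
    if col > 0 and b.x_min <= margin:
        x0 -= b.width
    if col < cols - 1 and b.x_max >= ts - margin:
        x1 += b.width
    if row > 0 and b.y_min <= margin:
        y0 -= b.height
    if row < rows - 1 and b.y_max >= ts - margin:
        y1 += b.height
    return Box(x0 + ox, y0 + oy, x1 + ox, y1 + oy, label=b.label, confidence=b.confidence)


def join(
    per_tile: Sequence[DetectionSet],
    tileset: TileSet,
    seam_nms_threshold: float = SEAM_MERGE_IOU,
    seam_margin: float = SEAM_MARGIN_DEFAULT,
) -> DetectionSet:
    """Re-project per-tile detections into the full frame and merge seams.

    Boxes strictly interior to their tile pass through untouched.  Boxes
    within ``seam_margin`` px of an interior border are candidates for
    seam merging: each is mirror-extended across the border it touches
    (see ``_extended``), and any pair of extensions exceeding
    ``seam_nms_threshold`` IoU is replaced by the union of the original
    boxes, keeping the higher confidence.  Set ``seam_margin`` to 0 to
    disable merging.  The result is clipped to the source frame.
    """
    if len(per_tile) != len(tileset.tiles):
        raise ValueError(
            f"got {len(per_tile)} detection sets for {len(tileset.tiles)} tiles"
        )
    W, H = tileset.source_size
    interior: list[Box] = []
    seam: list[tuple[Box, Box]] = []  # (frame box, mirror-extended frame box)
    for dets, (_, ox, oy) in zip(per_tile, tileset.tiles):
        for b in dets.boxes:
            moved = b.translated(ox, oy)
            if seam_margin > 0 and _near_seam(b, tileset, (ox, oy), seam_margin):
                seam.append((moved, _extended(b, tileset, (ox, oy), seam_margin)))
            else:
                interior.append(moved)

    merged: list[Box] = []
    pool = sorted(seam, key=lambda pair: -(pair[0].confidence or 0.0))
    while pool:
        top, top_ext = pool.pop(0)
        rest = []
        for other, other_ext in pool:
            if iou(top_ext, other_ext) > seam_nms_threshold:
                top = _union_box(top, other)
                top_ext = _union_box(top_ext, other_ext)
            else:
                rest.append((other, other_ext))
        pool = rest
        merged.append(top)

    clipped = [c for b in interior + merged if (c := b.clipped(W, H)) is not None]
    clipped.sort(key=lambda b: -(b.confidence or 0.0))
    return DetectionSet(clipped, (W, H))


def detect_tiled(
    predict: Callable[[np.ndarray], DetectionSet],
    image: np.ndarray,
    tile_size: int = 608,
    seam_nms_threshold: float = SEAM_MERGE_IOU,
    seam_margin: float = SEAM_MARGIN_DEFAULT,
) -> DetectionSet:
    """Full tiled inference: split, detect each tile, join.

    ``predict`` maps one tile image to a DetectionSet in tile coordinates
    (e.g. ``detector.predict``); it is invoked exactly once per tile.
    """
    tileset = split(image, tile_size)
    per_tile = [predict(tile) for tile, _, _ in tileset.tiles]
    return join(per_tile, tileset, seam_nms_threshold, seam_margin)
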