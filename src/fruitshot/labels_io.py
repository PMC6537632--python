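"""Annotation I/O (PASCAL VOC XML, DARKNET text) and label-aware image prep.

Internal convention everywhere: 0-based, half-open pixel coordinates.
VOC stores 1-based *inclusive* corners, so a VOC box ``(xmin..xmax)``
maps to internal ``[xmin - 1, xmax)``; DARKNET stores class index plus
center/size normalized by the image dimensions, printed to 6 decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .boxes import Box

__all__ = [
    "AnnotatedImage",
    "read_voc",
    "write_voc",
    "read_darknet",
    "write_darknet",
    "crop_band_and_resize",
    "load_image",
    "save_image",
]

# A clipped box keeping less than this fraction of its original area is dropped.
MIN_KEPT_AREA_FRACTION = 0.2


@dataclass
class AnnotatedImage:
    """An RGB image (H x W x 3 uint8 array) plus its ground-truth boxes."""

    image: np.ndarray
    boxes: list[Box] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H x W x 3, got shape {self.image.shape}")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def load_image(path: str | os.PathLike, boxes: list[Box] | None = None) -> AnnotatedImage:
    img = np.asarray(Image.open(path).convert("RGB"))
    return AnnotatedImage(img, boxes or [], source_id=Path(path).stem)


def save_image(a: AnnotatedImage, path: str | os.PathLike) -> None:
    Image.fromarray(a.image).save(path)


def read_voc(xml_source: str | os.PathLike | bytes) -> AnnotatedImage:
    """Parse a PASCAL VOC XML document into an AnnotatedImage.

    The returned image is a blank canvas of the annotated size unless the
    caller attaches pixels afterwards; box coordinates are converted from
    VOC's 1-based inclusive corners to internal half-open pixels.
    """
    if isinstance(xml_source, bytes):
        root = etree.fromstring(xml_source)
    else:
        root = etree.parse(str(xml_source)).getroot()

    size = root.find("size")
    if size is None:
        raise ValueError("VOC document lacks a <size> block")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))

    boxes: list[Box] = []
    for i, obj in enumerate(root.findall("object")):
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"object {i} lacks a <bndbox>")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"object {i} has xmax <= xmin or ymax <= ymin")
        boxes.append(Box(xmin - 1.0, ymin - 1.0, xmax, ymax, label=0))

    source_id = (root.findtext("filename") or "").rsplit(".", 1)[0]
    canvas = np.zeros((height, width, 3), dtype=np.uint8)
    return AnnotatedImage(canvas, boxes, source_id=source_id)


def write_voc(a: AnnotatedImage, class_name: str = "fruit") -> bytes:
    """Serialize annotations as PASCAL VOC XML (1-based inclusive corners)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{a.source_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(a.width)
    etree.SubElement(size, "height").text = str(a.height)
    etree.SubElement(size, "depth").text = "3"
    for b in a.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_name
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = _fmt(b.x_min + 1.0)
        etree.SubElement(bb, "ymin").text = _fmt(b.y_min + 1.0)
        etree.SubElement(bb, "xmax").text = _fmt(b.x_max)
        etree.SubElement(bb, "ymax").text = _fmt(b.y_max)
    return etree.tostring(root, pretty_print=True)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_darknet(a: AnnotatedImage) -> str:
    """DARKNET lines: ``class cx cy w h`` normalized to [0,1], 6 decimals."""
    lines = []
    for b in a.boxes:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > a.width or b.y_max > a.height:
            raise ValueError(f"box {b} exceeds image bounds {a.width}x{a.height}")
        cx, cy = b.center
        lines.append(
            f"{b.label} {cx / a.width:.6f} {cy / a.height:.6f} "
            f"{b.width / a.width:.6f} {b.height / a.height:.6f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_darknet(text: str, width: int, height: int, source_id: str = "") -> AnnotatedImage:
    boxes: list[Box] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        cls, cx, cy, w, h = line.split()
        cx, cy, w, h = (float(v) for v in (cx, cy, w, h))
        # 6-decimal normalized text can round a frame-edge box a fraction of
        # a pixel out of bounds; clamp back to the frame.
        x0 = max((cx - w / 2) * width, 0.0)
        y0 = max((cy - h / 2) * height, 0.0)
        x1 = min((cx + w / 2) * width, float(width))
        y1 = min((cy + h / 2) * height, float(height))
        if x1 <= x0 or y1 <= y0:
            continue
        boxes.append(Box(x0, y0, x1, y1, label=int(cls)))
    canvas = np.zeros((height, width, 3), dtype=np.uint8)
    return AnnotatedImage(canvas, boxes, source_id=source_id)


def clip_boxes(
    boxes: list[Box],
    width: float,
    height: float,
    min_kept_fraction: float = MIN_KEPT_AREA_FRACTION,
) -> list[Box]:
    """Clip boxes to the frame; drop a box when too little of it survives.

    The drop rule (remaining area < ``min_kept_fraction`` of the original,
    or under one square pixel) mirrors labeling only clearly visible fruit.
    Relative order is preserved.
    """
    out: list[Box] = []
    for b in boxes:
        c = b.clipped(width, height)
        if c is None or c.area < 1.0 or c.area < min_kept_fraction * b.area:
            continue
        out.append(c)
    return out


def crop_band_and_resize(
    a: AnnotatedImage,
    top_frac: float = 0.2,
    bottom_frac: float = 0.2,
    target: int = 608,
) -> AnnotatedImage:
    """Drop fruitless top/bottom bands, center-crop square, resize to target.

    Orchard photos framed on a whole tree waste roughly the top and bottom
    fifth on sky and ground; those bands are removed, the remainder is
    center-cropped to a square and rescaled to ``target x target``.  Boxes
    follow the same affine map, are clipped, and are dropped when they fell
    (almost) entirely inside a removed band.
    """
    if not (0.0 <= top_frac and 0.0 <= bottom_frac and top_frac + bottom_frac < 1.0):
        raise ValueError("need 0 <= top_frac + bottom_frac < 1")
    if target < 1:
        raise ValueError("target must be positive")

    H, W = a.height, a.width
    y0 = int(round(top_frac * H))
    y1 = H - int(round(bottom_frac * H))
    band_h = y1 - y0
    if band_h < 1:
        raise ValueError("crop removes the whole image")

    side = min(band_h, W)
    x0 = (W - side) // 2
    yc = y0 + (band_h - side) // 2
    region = a.image[yc : yc + side, x0 : x0 + side]

    scale = target / side
    resized = np.asarray(
        Image.fromarray(region).resize((target, target), Image.BILINEAR)
    )

    moved = [
        Box(
            (b.x_min - x0) * scale,
            (b.y_min - yc) * scale,
            (b.x_max - x0) * scale,
            (b.y_max - yc) * scale,
            label=b.label,
            confidence=b.confidence,
        )
        for b in a.boxes
    ]
    return AnnotatedImage(resized, clip_boxes(moved, target, target), source_id=a.source_id)
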