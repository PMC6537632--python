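"""Synthetic orchard-scene generator with exact ground-truth boxes.

Each scene is a flat cartoon of a fruit-tree canopy viewed from the row:
a bluish sky band over brownish soil, a cloud of dark-green elliptic
leaves, and light-green / light-red circular fruits drawn on top.  Every
visible fruit contributes one ground-truth box (the tight bounding square
of its circle, clipped to the canvas), so the labels are exact by
construction — no manual annotation noise.  Generation is fully
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .boxes import Box
from .labels_io import AnnotatedImage, save_image, write_darknet, write_voc

__all__ = ["SceneConfig", "cpu_scene_config", "generate_scene", "generate_dataset"]

# Fraction of a fruit disc that must remain visible (not covered by
# later-drawn fruits) for the fruit to keep its ground-truth box.
MIN_VISIBLE_FRACTION = 0.2


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic orchard scene.

    Color ranges are inclusive (low, high) per RGB channel; geometric
    ranges are inclusive integer ranges.  Defaults reproduce a 608 x 608
    canvas with roughly 50 fruits in moderate leaf clutter.
    """

    canvas_size: int = 608
    sky_fraction: float = 0.5
    n_leaves: tuple[int, int] = (150, 400)
    n_fruits: tuple[int, int] = (30, 70)
    fruit_radius: tuple[int, int] = (14, 28)
    leaf_axes: tuple[int, int] = (10, 40)
    sky_color: tuple[tuple[int, int], ...] = ((100, 160), (150, 200), (220, 255))
    soil_color: tuple[tuple[int, int], ...] = ((90, 140), (60, 90), (30, 60))
    leaf_color: tuple[tuple[int, int], ...] = ((0, 60), (90, 140), (0, 60))
    fruit_green: tuple[tuple[int, int], ...] = ((140, 190), (200, 240), (120, 170))
    fruit_red: tuple[tuple[int, int], ...] = ((200, 255), (80, 130), (80, 130))
    occlusion_allowed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_size <= 0:
            raise ValueError("canvas_size must be positive")
        if not (0.0 < self.sky_fraction < 1.0):
            raise ValueError("sky_fraction must lie in (0, 1)")
        for name in ("n_leaves", "n_fruits", "fruit_radius", "leaf_axes"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or negative")
        if self.fruit_radius[1] >= self.canvas_size:
            raise ValueError("fruit radius must be smaller than the canvas")


def cpu_scene_config(seed: int = 0) -> SceneConfig:
    """Scene conditions for CPU-scale (208 px, 13-grid) experiments.

    Geometry scales linearly from the 608-px defaults (fruit radius 14-28
    becomes 5-10 px); the fruit count scales with the number of grid cells
    (13^2 / 26^2 = 1/4 of the full-scale 30-70) so the fraction of occupied
    cells — the quantity the detector actually resolves — stays the same.
    """
    return SceneConfig(
        canvas_size=208,
        n_leaves=(20, 60),
        n_fruits=(8, 16),
        fruit_radius=(5, 10),
        leaf_axes=(4, 14),
        seed=seed,
    )


def _pick_color(rng: np.random.Generator, ranges) -> tuple[int, int, int]:
    return tuple(int(rng.integers(lo, hi + 1)) for lo, hi in ranges)


def generate_scene(cfg: SceneConfig, seed: int | None = None) -> AnnotatedImage:
    """Render one scene; returns the image with exact fruit boxes.

    Drawing order: backgrounds, leaves, then fruits, so fruits sit on top
    of foliage the way ripe fruit reads against a canopy.  When fruits may
    overlap each other (``occlusion_allowed``), a fruit buried under
    later-drawn fruits keeps its box only while at least 20% of its disc
    stays visible — mirroring the practice of labeling only visible fruit.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    S = cfg.canvas_size

    img = Image.new("RGB", (S, S))
    draw = ImageDraw.Draw(img)
    horizon = int(round(cfg.sky_fraction * S))
    draw.rectangle([0, 0, S - 1, horizon - 1], fill=_pick_color(rng, cfg.sky_color))
    draw.rectangle([0, horizon, S - 1, S - 1], fill=_pick_color(rng, cfg.soil_color))

    n_leaves = int(rng.integers(cfg.n_leaves[0], cfg.n_leaves[1] + 1))
    for _ in range(n_leaves):
        ax = int(rng.integers(cfg.leaf_axes[0], cfg.leaf_axes[1] + 1))
        ay = int(rng.integers(cfg.leaf_axes[0], cfg.leaf_axes[1] + 1))
        cx = int(rng.integers(0, S))
        cy = int(rng.integers(0, S))
        draw.ellipse(
            [cx - ax, cy - ay, cx + ax, cy + ay],
            fill=_pick_color(rng, cfg.leaf_color),
        )

    n_fruits = int(rng.integers(cfg.n_fruits[0], cfg.n_fruits[1] + 1))
    # Index mask tracks which fruit owns each pixel after all drawing, so
    # visibility of each disc can be measured exactly.
    owner = np.full((S, S), -1, dtype=np.int32)
    yy, xx = np.mgrid[0:S, 0:S]
    discs: list[tuple[int, int, int]] = []

    placed = 0
    attempts = 0
    while placed < n_fruits and attempts < 50 * max(n_fruits, 1):
        attempts += 1
        r = int(rng.integers(cfg.fruit_radius[0], cfg.fruit_radius[1] + 1))
        cx = int(rng.integers(0, S))
        cy = int(rng.integers(0, S))
        palette = cfg.fruit_green if rng.random() < 0.5 else cfg.fruit_red
        color = _pick_color(rng, palette)
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if not cfg.occlusion_allowed and np.any(owner[disc] >= 0):
            continue
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color)
        owner[disc] = placed
        discs.append((cx, cy, r))
        placed += 1

    boxes: list[Box] = []
    for i, (cx, cy, r) in enumerate(discs):
        disc_area = np.count_nonzero((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r)
        visible = np.count_nonzero(owner == i)
        if disc_area == 0 or visible < MIN_VISIBLE_FRACTION * disc_area:
            continue
        b = Box(cx - r, cy - r, cx + r + 1, cy + r + 1).clipped(S, S)
        if b is not None:
            boxes.append(b)

    return AnnotatedImage(np.asarray(img), boxes, source_id="scene")


def generate_dataset(
    cfg: SceneConfig,
    n_images: int,
    out_dir: str | Path,
    label_format: str = "darknet",
    master_seed: int | None = None,
) -> list[dict]:
    """Write ``n_images`` scenes plus labels; returns the manifest.

    Per-scene seeds are drawn from a seed sequence spawned from the master
    seed, so regenerating with the same arguments reproduces every file
    byte for byte.  The manifest (also written as ``manifest.json``) lists
    the image/label path pair and seed of every scene.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if label_format not in ("darknet", "voc"):
        raise ValueError(f"unknown label format {label_format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(cfg.seed if master_seed is None else master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_images)]

    manifest = []
    for i, s in enumerate(seeds):
        scene = generate_scene(cfg, seed=s)
        scene.source_id = f"scene_{i:04d}"
        img_path = out / f"{scene.source_id}.png"
        save_image(scene, img_path)
        if label_format == "darknet":
            lbl_path = out / f"{scene.source_id}.txt"
            lbl_path.write_text(write_darknet(scene))
        else:
            lbl_path = out / f"{scene.source_id}.xml"
            lbl_path.write_bytes(write_voc(scene))
        manifest.append(
            {"image": img_path.name, "labels": lbl_path.name, "seed": s, "n_boxes": len(scene.boxes)}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
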