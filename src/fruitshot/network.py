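"""Grid-detector variants: layer specs, training, and inference.

The detector follows the single-shot recipe: a convolutional stack maps a
square RGB input to an S x S grid; every cell owns B anchor slots, each
predicting center offsets (through a sigmoid, so the center stays inside
the cell), log-scale size offsets relative to the anchor prior, and an
objectness logit; C class logits are shared per cell, giving the output
tensor S x S x (C + B*5).

Shipped variants:

* ``fine_grid_spec`` (M1): 23 layers with pooling, 608 input, 26 x 26 grid —
  a finer grid than the stock 13 x 13 so one cell is roughly one fruit.
* ``shallow_spec`` (M2): 11 layers, no pooling; downsampling is done by
  strided convolutions instead.  Same 26 x 26 grid.
* ``tiny_spec``: a 6-layer, 208-input, 13 x 13-grid variant of the same
  design for CPU-scale experiments.

26 does not divide 608, so the reduction chain cannot be all stride-2:
three stride-2 stages (608 -> 304 -> 152 -> 76) are followed by one
stride-3, kernel-3, pad-1 stage (76 -> 26).  The cell size in pixels is
therefore the real number 608/26, which decoding uses as-is.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .boxes import AnchorSet, Box, RawPrediction, decode, nms
from .labels_io import AnnotatedImage
from .tiler import DetectionSet

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "LossWeights",
    "spatial_dims",
    "prelu",
    "build",
    "loss",
    "train",
    "fine_grid_spec",
    "shallow_spec",
    "tiny_spec",
    "Detector",
    "save_checkpoint",
    "load_checkpoint",
]


def prelu(x, alpha: float = 0.1):
    """Parametric ReLU, element-wise max(alpha*x, x); 0 < alpha < 1."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return np.maximum(np.multiply(alpha, x), x)


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | pool | detect_head
    filters: int = 0  # output channels (conv / detect_head)
    kernel: int = 1
    stride: int = 1
    pad: int = 0
    activation: str = "prelu"  # prelu | linear

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool", "detect_head"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if self.kind in ("conv", "detect_head") and self.filters < 1:
            raise ValueError("conv layers need filters >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    input_size: int = 608
    grid_size: int = 26
    classes: int = 1
    num_anchors: int = 5

    @property
    def output_depth(self) -> int:
        return self.classes + self.num_anchors * 5

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: Adam at learning rate 0.002, 35 epochs of 60 optimizer steps
    each (the dataset is sampled with replacement when shorter than
    steps x batch).  Fine-tuning from a checkpoint typically uses 5 epochs;
    ``freeze_backbone`` turns the net into a fixed feature extractor whose
    non-head weights stay bit-identical through training.
    """

    learning_rate: float = 0.002
    epochs: int = 35
    steps: int = 60
    batch_size: int = 8
    freeze_backbone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class LossWeights:
    coord: float = 5.0
    obj: float = 1.0
    noobj: float = 0.5
    cls: float = 1.0


def spatial_dims(spec: NetworkSpec) -> list[tuple[int, int, int]]:
    """Per-layer (channels, height, width) from the reduction formula.

    Each layer maps n -> (n + 2*pad - F) / S + 1; a non-integer result is
    a spec error naming the layer.  The final spatial size must equal the
    declared grid and the final depth must equal C + B*5.
    """
    p, n = 3, spec.input_size
    dims: list[tuple[int, int, int]] = []
    for i, layer in enumerate(spec.layers):
        num = n + 2 * layer.pad - layer.kernel
        if num < 0 or num % layer.stride != 0:
            raise ValueError(
                f"layer {i} ({layer.kind} F={layer.kernel} S={layer.stride} "
                f"pad={layer.pad}) maps size {n} to non-integer "
                f"{n + 2 * layer.pad - layer.kernel}/{layer.stride} + 1"
            )
        n = num // layer.stride + 1
        if layer.kind in ("conv", "detect_head"):
            p = layer.filters
        dims.append((p, n, n))
    if n != spec.grid_size:
        raise ValueError(f"spec {spec.name} ends at grid {n}, declared {spec.grid_size}")
    if p != spec.output_depth:
        raise ValueError(
            f"spec {spec.name} ends with depth {p}, expected C + B*5 = {spec.output_depth}"
        )
    return dims


def _conv_layers(widths_and_shapes: list[tuple], head_filters: int) -> tuple[LayerSpec, ...]:
    layers = [LayerSpec("conv", f, k, s, p) for f, k, s, p in widths_and_shapes]
    layers.append(LayerSpec("detect_head", head_filters, 1, 1, 0, activation="linear"))
    return tuple(layers)


def fine_grid_spec(classes: int = 1, num_anchors: int = 5) -> NetworkSpec:
    """M1: the 23-layer fine-grid model (608 input -> 26 x 26)."""
    d = classes + num_anchors * 5
    layers: list[LayerSpec] = [
        LayerSpec("conv", 32, 3, 1, 1),
        LayerSpec("pool", kernel=2, stride=2),  # 304
        LayerSpec("conv", 64, 3, 1, 1),
        LayerSpec("pool", kernel=2, stride=2),  # 152
        LayerSpec("conv", 128, 3, 1, 1),
        LayerSpec("conv", 64, 1, 1, 0),
        LayerSpec("conv", 128, 3, 1, 1),
        LayerSpec("pool", kernel=2, stride=2),  # 76
        LayerSpec("conv", 256, 3, 1, 1),
        LayerSpec("conv", 128, 1, 1, 0),
        LayerSpec("conv", 256, 3, 1, 1),
        LayerSpec("conv", 256, 3, 3, 1),  # 76 -> 26 (stride 3)
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 256, 1, 1, 0),
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 256, 1, 1, 0),
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 512, 1, 1, 0),
        LayerSpec("conv", 512, 3, 1, 1),
        LayerSpec("conv", 512, 1, 1, 0),
        LayerSpec("detect_head", d, 1, 1, 0, activation="linear"),
    ]
    return NetworkSpec("M1", tuple(layers), 608, 26, classes, num_anchors)


def shallow_spec(classes: int = 1, num_anchors: int = 5) -> NetworkSpec:
    """M2: 11 layers, pool-free; strided convolutions downsample instead.

    Stride-2 stages use 4 x 4 kernels (pad 1): with an even input size a
    stride-2 window must have even extent for the reduction formula to
    stay integral.
    """
    d = classes + num_anchors * 5
    layers = _conv_layers(
        [
            (16, 4, 2, 1),  # 608 -> 304
            (32, 3, 1, 1),
            (32, 4, 2, 1),  # -> 152
            (64, 3, 1, 1),
            (64, 4, 2, 1),  # -> 76
            (128, 3, 3, 1),  # -> 26
            (256, 3, 1, 1),
            (512, 3, 1, 1),
            (512, 1, 1, 0),
            (512, 3, 1, 1),
        ],
        d,
    )
    return NetworkSpec("M2", layers, 608, 26, classes, num_anchors)


def tiny_spec(classes: int = 1, num_anchors: int = 5) -> NetworkSpec:
    """A 6-layer, 208-input, 13-grid variant for CPU-scale training runs."""
    d = classes + num_anchors * 5
    layers = _conv_layers(
        [
            (16, 4, 2, 1),  # 208 -> 104
            (32, 4, 2, 1),  # -> 52
            (64, 4, 2, 1),  # -> 26
            (96, 4, 2, 1),  # -> 13
            (128, 3, 1, 1),
        ],
        d,
    )
    return NetworkSpec("tiny", layers, 208, 13, classes, num_anchors)


SPECS = {"m1": fine_grid_spec, "fine_grid": fine_grid_spec, "m2": shallow_spec, "shallow": shallow_spec, "tiny": tiny_spec}


class Detector:
    """A built detector: the layer stack plus its spec and anchor priors."""

    def __init__(self, spec: NetworkSpec, anchors: AnchorSet | None = None, seed: int = 0):
        self.spec = spec
        self.anchors = anchors or AnchorSet()
        if len(self.anchors) != spec.num_anchors:
            raise ValueError(
                f"spec declares {spec.num_anchors} anchors, got {len(self.anchors)} priors"
            )
        spatial_dims(spec)  # raises on inconsistent specs
        rng = np.random.default_rng(seed)
        stack: list = []
        in_ch = 3
        for layer in spec.layers:
            if layer.kind == "pool":
                stack.append(nn.MaxPool2D(layer.kernel, layer.stride))
                continue
            stack.append(nn.Conv2D(in_ch, layer.filters, layer.kernel, layer.stride, layer.pad, rng=rng))
            in_ch = layer.filters
            if layer.activation == "prelu":
                stack.append(nn.PReLU(0.1))
        self.net = nn.Sequential(stack)

    # -- plumbing -----------------------------------------------------------
    def _head_conv(self) -> nn.Conv2D:
        return [l for l in self.net.layers if isinstance(l, nn.Conv2D)][-1]

    def freeze_backbone(self) -> None:
        head = self._head_conv()
        for l in self.net.layers:
            if isinstance(l, nn.Conv2D) and l is not head:
                l.frozen = True

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, 3, H, W) float32 input to (N, C + B*5, S, S) raw output."""
        if batch.shape[2] != self.spec.input_size or batch.shape[3] != self.spec.input_size:
            raise ValueError(
                f"input {batch.shape[2]}x{batch.shape[3]} does not match "
                f"spec input_size {self.spec.input_size}"
            )
        return self.net.forward(batch.astype(np.float32), train=train)

    @staticmethod
    def preprocess(image: np.ndarray) -> np.ndarray:
        """uint8 H x W x 3 -> float32 1 x 3 x H x W in [-0.5, 0.5]."""
        x = image.astype(np.float32) / 255.0 - 0.5
        return x.transpose(2, 0, 1)[None]

    def predict(
        self,
        image: np.ndarray,
        conf_threshold: float = 0.25,
        nms_threshold: float | None = 0.45,
    ) -> DetectionSet:
        """Decode, threshold and suppress one image's detections.

        ``nms_threshold=None`` disables suppression (every above-threshold
        grid slot becomes a detection).  Inference is deterministic.
        """
        S = self.spec.grid_size
        B = self.spec.num_anchors
        size = self.spec.input_size
        if image.shape[0] != size or image.shape[1] != size:
            raise ValueError(f"image {image.shape[1]}x{image.shape[0]}, expected {size}x{size}")
        raw = self.forward(self.preprocess(image))[0]  # (C+B*5, S, S)
        dets: list[Box] = []
        anchor_part = raw[: B * 5].reshape(B, 5, S, S)
        class_part = raw[B * 5 :]  # (C, S, S)
        for a in range(B):
            for row in range(S):
                for col in range(S):
                    rp = RawPrediction(
                        t_x=float(anchor_part[a, 0, row, col]),
                        t_y=float(anchor_part[a, 1, row, col]),
                        t_w=float(anchor_part[a, 2, row, col]),
                        t_h=float(anchor_part[a, 3, row, col]),
                        objectness=float(anchor_part[a, 4, row, col]),
                        grid_col=col,
                        grid_row=row,
                        anchor_index=a,
                        class_scores=tuple(float(v) for v in class_part[:, row, col]),
                    )
                    box = decode(rp, self.anchors, S, size)
                    if box.confidence >= conf_threshold:
                        clipped = box.clipped(size, size)
                        if clipped is not None:
                            dets.append(clipped)
        if nms_threshold is not None:
            dets = nms(dets, nms_threshold)
        else:
            dets.sort(key=lambda b: -(b.confidence or 0.0))
        return DetectionSet(dets, (size, size))


def build(spec: NetworkSpec, anchors: AnchorSet | None = None, seed: int = 0) -> Detector:
    """Build a detector with randomly initialized kernels and biases."""
    return Detector(spec, anchors, seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _encode_targets(
    truth_sets: list[list[Box]],
    spec: NetworkSpec,
    anchors: AnchorSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Assignment + regression targets for a batch.

    Returns (mask, target) of shape (N, B, 6, S, S): channel order
    tx, ty, tw, th, obj, cls; mask flags responsible anchor slots.  Each
    truth is assigned to its center cell and the prior of highest IoU
    against the truth's size (both centered); a later truth landing on an
    occupied slot overwrites it.
    """
    S, Bn = spec.grid_size, spec.num_anchors
    N = len(truth_sets)
    cell = spec.input_size / S
    mask = np.zeros((N, Bn, S, S), dtype=bool)
    tgt = np.zeros((N, Bn, 6, S, S), dtype=np.float32)
    priors = np.array(anchors.priors)
    for i, truths in enumerate(truth_sets):
        for b in truths:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > spec.input_size or b.y_max > spec.input_size:
                raise ValueError(f"truth box {b} outside the {spec.input_size}px image")
            cx, cy = b.center
            col = min(int(cx / cell), S - 1)
            row = min(int(cy / cell), S - 1)
            w, h = b.width / cell, b.height / cell
            inter = np.minimum(priors[:, 0], w) * np.minimum(priors[:, 1], h)
            union = priors[:, 0] * priors[:, 1] + w * h - inter
            a = int(np.argmax(inter / union))
            mask[i, a, row, col] = True
            tgt[i, a, 0, row, col] = cx / cell - col
            tgt[i, a, 1, row, col] = cy / cell - row
            tgt[i, a, 2, row, col] = np.log(w / priors[a, 0])
            tgt[i, a, 3, row, col] = np.log(h / priors[a, 1])
            tgt[i, a, 4, row, col] = 1.0
            tgt[i, a, 5, row, col] = 1.0
    return mask, tgt


def loss(
    raw: np.ndarray,
    truth_sets: list[list[Box]],
    anchors: AnchorSet,
    spec: NetworkSpec,
    weights: LossWeights = LossWeights(),
) -> tuple[float, np.ndarray]:
    """Multi-part squared-error detection objective and its raw-output gradient.

    Terms (all squared errors, summed over the grid, averaged over the
    batch): coordinates of responsible slots in sigma/log space (weight
    ``coord``); objectness toward 1 on responsible slots (``obj``) and
    toward 0 elsewhere (``noobj``, down-weighted so the empty sky does not
    drown the fruit); class score toward 1 on object cells (``cls``).
    """
    N = raw.shape[0]
    S, Bn, C = spec.grid_size, spec.num_anchors, spec.classes
    mask, tgt = _encode_targets(truth_sets, spec, anchors)
    anchor_part = raw[:, : Bn * 5].reshape(N, Bn, 5, S, S)
    class_part = raw[:, Bn * 5 :]  # (N, C, S, S)

    sig_xy = _sigmoid(anchor_part[:, :, 0:2])
    sig_obj = _sigmoid(anchor_part[:, :, 4])
    sig_cls = _sigmoid(class_part)

    m = mask[:, :, None]  # broadcast over the channel axis
    # Coordinates: sigma-space for x/y, raw log-space for w/h.
    d_xy = (sig_xy - tgt[:, :, 0:2]) * m
    d_wh = (anchor_part[:, :, 2:4] - tgt[:, :, 2:4]) * m
    # Objectness.
    d_obj_pos = (sig_obj - 1.0) * mask
    d_obj_neg = sig_obj * (~mask)
    # Class: object cells are cells with any responsible slot.
    obj_cells = mask.any(axis=1)  # (N, S, S)
    d_cls = (sig_cls - 1.0) * obj_cells[:, None]

    total = (
        weights.coord * (np.sum(d_xy**2) + np.sum(d_wh**2))
        + weights.obj * np.sum(d_obj_pos**2)
        + weights.noobj * np.sum(d_obj_neg**2)
        + weights.cls * np.sum(d_cls**2)
    ) / N

    # Gradient w.r.t. raw outputs: chain through sigmoid where applied.
    g_anchor = np.zeros_like(anchor_part)
    g_anchor[:, :, 0:2] = 2 * weights.coord * d_xy * sig_xy * (1 - sig_xy)
    g_anchor[:, :, 2:4] = 2 * weights.coord * d_wh
    g_anchor[:, :, 4] = 2 * (
        weights.obj * d_obj_pos + weights.noobj * d_obj_neg
    ) * sig_obj * (1 - sig_obj)
    g_class = 2 * weights.cls * d_cls * sig_cls * (1 - sig_cls)

    grad = np.concatenate(
        [g_anchor.reshape(N, Bn * 5, S, S), g_class], axis=1
    ).astype(np.float32) / N
    return float(total), grad


def _dataset_arrays(dataset: list[AnnotatedImage], spec: NetworkSpec) -> tuple[np.ndarray, list[list[Box]]]:
    for a in dataset:
        if a.width != spec.input_size or a.height != spec.input_size:
            raise ValueError(
                f"image {a.source_id} is {a.width}x{a.height}, spec wants {spec.input_size}"
            )
        for b in a.boxes:
            if b.label != 0:
                raise ValueError("training labels must be single-class (index 0)")
    x = np.stack([Detector.preprocess(a.image)[0] for a in dataset])
    return x, [a.boxes for a in dataset]


def train(
    detector: Detector,
    dataset: list[AnnotatedImage],
    cfg: TrainConfig,
    val: list[AnnotatedImage] | None = None,
    weights: LossWeights = LossWeights(),
    conf_threshold: float = 0.25,
) -> list[dict]:
    """Train in place; returns the per-epoch log.

    Each epoch runs ``cfg.steps`` Adam updates on batches sampled with
    replacement (seeded).  With ``freeze_backbone`` every non-head conv
    keeps its initial weights — the fixed-feature-extractor transfer mode.
    When a validation set is supplied, held-out F1 at IoU 0.5 is logged
    per epoch.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    from .evaluate import match  # local import: evaluate is a leaf module

    if cfg.freeze_backbone:
        detector.freeze_backbone()
    x_all, truths_all = _dataset_arrays(dataset, detector.spec)
    opt = nn.Adam(detector.net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(cfg.steps):
            idx = rng.integers(0, len(dataset), size=min(cfg.batch_size, len(dataset)))
            batch = x_all[idx]
            truths = [truths_all[i] for i in idx]
            raw = detector.forward(batch, train=True)
            value, grad = loss(raw, truths, detector.anchors, detector.spec, weights)
            detector.net.zero_grad()
            detector.net.backward(grad)
            opt.step()
            losses.append(value)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val is not None:
            tp = fp = fn = 0
            for a in val:
                dets = detector.predict(a.image, conf_threshold=conf_threshold)
                m = match(dets, a.boxes, 0.5)
                tp += m.tp
                fp += m.fp
                fn += m.fn
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            entry["val_f1"] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        log.append(entry)
    return log


def save_checkpoint(detector: Detector, path) -> None:
    """Single-file checkpoint: weights plus the spec (hash-embedded)."""
    spec_json = json.dumps(asdict_spec(detector.spec), sort_keys=True)
    arrays = {}
    convs = [l for l in detector.net.layers if isinstance(l, nn.Conv2D)]
    for i, c in enumerate(convs):
        arrays[f"W{i}"] = c.W
        arrays[f"b{i}"] = c.b
    arrays["anchors"] = np.array(detector.anchors.priors)
    import hashlib

    arrays["spec_json"] = np.frombuffer(spec_json.encode(), dtype=np.uint8)
    arrays["spec_hash"] = np.frombuffer(
        hashlib.sha256(spec_json.encode()).digest(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def asdict_spec(spec: NetworkSpec) -> dict:
    d = asdict(spec)
    d["layers"] = [asdict(l) for l in spec.layers]
    return d


def spec_from_dict(d: dict) -> NetworkSpec:
    layers = tuple(LayerSpec(**l) for l in d["layers"])
    return NetworkSpec(
        d["name"], layers, d["input_size"], d["grid_size"], d["classes"], d["num_anchors"]
    )


def load_checkpoint(path) -> Detector:
    data = np.load(path)
    spec_json = bytes(data["spec_json"]).decode()
    spec = spec_from_dict(json.loads(spec_json))
    anchors = AnchorSet(tuple((float(w), float(h)) for w, h in data["anchors"]))
    det = Detector(spec, anchors, seed=0)
    convs = [l for l in det.net.layers if isinstance(l, nn.Conv2D)]
    for i, c in enumerate(convs):
        c.W[...] = data[f"W{i}"]
        c.b[...] = data[f"b{i}"]
    return det
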