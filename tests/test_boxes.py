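"""Geometry unit tests: IoU, decoding, NMS, anchor fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitshot.boxes import AnchorSet, Box, RawPrediction, decode, fit_anchors, iou, nms


def raster_iou(a: Box, b: Box, res: int = 20) -> float:
    """Independent IoU oracle: count sub-pixel samples inside each box."""
    x0 = min(a.x_min, b.x_min)
    y0 = min(a.y_min, b.y_min)
    x1 = max(a.x_max, b.x_max)
    y1 = max(a.y_max, b.y_max)
    xs = np.linspace(x0, x1, int((x1 - x0) * res), endpoint=False) + 0.5 / res
    ys = np.linspace(y0, y1, int((y1 - y0) * res), endpoint=False) + 0.5 / res
    X, Y = np.meshgrid(xs, ys)
    in_a = (X >= a.x_min) & (X < a.x_max) & (Y >= a.y_min) & (Y < a.y_max)
    in_b = (X >= b.x_min) & (X < b.x_max) & (Y >= b.y_min) & (Y < b.y_max)
    union = np.count_nonzero(in_a | in_b)
    return np.count_nonzero(in_a & in_b) / union if union else 0.0


class TestIoU:
    def test_identical_boxes(self):
        b = Box(0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 10, 10), Box(20, 20, 30, 30)) == 0.0

    def test_half_overlap_matches_rasterization(self):
        a, b = Box(0, 0, 10, 10), Box(5, 0, 15, 10)
        # analytic: inter 50, union 150
        assert iou(a, b) == pytest.approx(50 / 150)
        assert iou(a, b) == pytest.approx(raster_iou(a, b), abs=5e-3)

    def test_random_pairs_match_rasterization(self, rng):
        for _ in range(50):
            x0, y0, x1, y1 = rng.uniform(0, 30, 4)
            a = Box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
            x0, y0, x1, y1 = rng.uniform(0, 30, 4)
            b = Box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
            assert iou(a, b) == pytest.approx(raster_iou(a, b), abs=1e-2)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(5, 0, 5, 10)

    @given(
        st.tuples(*[st.floats(0, 50) for _ in range(4)]),
        st.tuples(*[st.floats(0, 50) for _ in range(4)]),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_bounded(self, p, q):
        a = Box(min(p[0], p[2]), min(p[1], p[3]), max(p[0], p[2]) + 1, max(p[1], p[3]) + 1)
        b = Box(min(q[0], q[2]), min(q[1], q[3]), max(q[0], q[2]) + 1, max(q[1], q[3]) + 1)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestDecode:
    def test_zero_logits_center_of_cell(self):
        raw = RawPrediction(0, 0, 0, 0, 0, grid_col=0, grid_row=0, anchor_index=0)
        box = decode(raw, AnchorSet(((1.0, 1.0),)), grid_size=4, image_size=4)
        # cell size 1 px: center (0.5, 0.5), size 1x1
        assert box.center == pytest.approx((0.5, 0.5))
        assert (box.width, box.height) == pytest.approx((1.0, 1.0))

    def test_fine_grid_pixel_arithmetic(self):
        raw = RawPrediction(0, 0, 0, 0, 0, grid_col=12, grid_row=12, anchor_index=0)
        box = decode(raw, AnchorSet(((1.0, 1.0),)), grid_size=26, image_size=608)
        expected = 12.5 * 608 / 26
        assert box.center == pytest.approx((expected, expected))

    def test_center_always_inside_source_cell(self, rng):
        anchors = AnchorSet()
        for _ in range(1000):
            col, row = (int(v) for v in rng.integers(0, 13, 2))
            raw = RawPrediction(
                *rng.normal(0, 3, 4),
                objectness=float(rng.normal()),
                grid_col=col,
                grid_row=row,
                anchor_index=int(rng.integers(0, 5)),
            )
            box = decode(raw, anchors, grid_size=13, image_size=208)
            cell = 208 / 13
            cx, cy = box.center
            assert col * cell <= cx <= (col + 1) * cell
            assert row * cell <= cy <= (row + 1) * cell

    def test_width_monotone_in_tw(self):
        widths = []
        for tw in (-1.0, 0.0, 1.0, 2.0):
            raw = RawPrediction(0, 0, tw, 0, 0, grid_col=0, grid_row=0, anchor_index=0)
            widths.append(decode(raw, AnchorSet(((1.0, 1.0),)), 13, 208).width)
        assert widths == sorted(widths)
        assert len(set(widths)) == len(widths)

    def test_confidence_is_sigmoid_product(self):
        raw = RawPrediction(0, 0, 0, 0, objectness=0.0, grid_col=0, grid_row=0, anchor_index=0, class_scores=(0.0,))
        box = decode(raw, AnchorSet(((1.0, 1.0),)), 13, 208)
        assert box.confidence == pytest.approx(0.25)


def brute_force_nms(boxes, thr):
    kept = []
    for cand in sorted(boxes, key=lambda b: -b.confidence):
        if not any(iou(cand, k) > thr for k in kept):
            kept.append(cand)
    return kept


class TestNMS:
    def test_single_box_passthrough(self):
        b = Box(0, 0, 5, 5, confidence=0.7)
        assert nms([b], 0.5) == [b]

    def test_duplicate_keeps_higher_confidence(self):
        hi = Box(0, 0, 10, 10, confidence=0.9)
        lo = Box(0, 0, 10, 10, confidence=0.8)
        assert nms([lo, hi], 0.5) == [hi]

    def test_matches_brute_force_on_random_sets(self, rng):
        for trial in range(10):
            boxes = []
            for _ in range(20):
                x, y = rng.uniform(0, 50, 2)
                w, h = rng.uniform(2, 15, 2)
                boxes.append(Box(x, y, x + w, y + h, confidence=float(rng.uniform(0.01, 1))))
            assert nms(boxes, 0.5) == brute_force_nms(boxes, 0.5)

    def test_subset_and_idempotent(self, rng):
        boxes = [
            Box(x, x, x + 10, x + 10, confidence=float(c))
            for x, c in zip(rng.uniform(0, 20, 15), rng.uniform(0.1, 1, 15))
        ]
        out = nms(boxes, 0.4)
        assert all(b in boxes for b in out)
        assert nms(out, 0.4) == out

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nms([Box(0, 0, 1, 1, confidence=0.5)], 1.5)

    def test_confidence_required(self):
        with pytest.raises(ValueError):
            nms([Box(0, 0, 1, 1)], 0.5)


def test_fit_anchors_recovers_two_size_clusters(rng):
    boxes = []
    for _ in range(100):
        cx, cy = rng.uniform(50, 150, 2)
        r = 8 if rng.random() < 0.5 else 32
        boxes.append(Box(cx - r, cy - r, cx + r, cy + r))
    anchors = fit_anchors(boxes, 2, cell_size=16.0, seed=0)
    sizes = sorted(w for w, h in anchors.priors)
    assert sizes[0] == pytest.approx(1.0, abs=0.1)
    assert sizes[1] == pytest.approx(4.0, abs=0.4)
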