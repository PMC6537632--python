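"""Detector specs, layer arithmetic, loss, gradients and training contracts."""

import numpy as np
import pytest

from fruitshot.boxes import AnchorSet, Box
from fruitshot.labels_io import AnnotatedImage
from fruitshot.network import (
    Detector,
    LayerSpec,
    LossWeights,
    NetworkSpec,
    TrainConfig,
    build,
    fine_grid_spec,
    load_checkpoint,
    loss,
    prelu,
    save_checkpoint,
    shallow_spec,
    spatial_dims,
    tiny_spec,
    train,
)
from fruitshot.synthgen import cpu_scene_config, generate_scene


def micro_spec(input_size=16, grid=4):
    """A 3-layer spec small enough for numeric gradient checking."""
    layers = (
        LayerSpec("conv", 4, 4, 2, 1),  # 16 -> 8
        LayerSpec("conv", 6, 4, 2, 1),  # 8 -> 4
        LayerSpec("detect_head", 26, 1, 1, 0, activation="linear"),
    )
    return NetworkSpec("micro", layers, input_size, grid, 1, 5)


class TestSpatialDims:
    def test_pool_reduction_formula(self):
        spec = NetworkSpec(
            "p", (LayerSpec("pool", kernel=2, stride=2), LayerSpec("detect_head", 26, 1)), 608, 304
        )
        assert spatial_dims(spec)[0][1] == 304

    def test_identity_layer_keeps_dims(self):
        spec = NetworkSpec(
            "i", (LayerSpec("conv", 8, 1, 1, 0), LayerSpec("detect_head", 26, 1)), 32, 32
        )
        dims = spatial_dims(spec)
        assert dims[0] == (8, 32, 32)

    def test_fine_grid_spec_reaches_26(self):
        assert spatial_dims(fine_grid_spec())[-1] == (26, 26, 26)

    def test_shallow_spec_reaches_26_with_11_layers(self):
        spec = shallow_spec()
        assert spec.n_layers == 11
        assert all(l.kind != "pool" for l in spec.layers)
        assert spatial_dims(spec)[-1][1] == 26

    def test_non_integer_dimension_names_layer(self):
        spec = NetworkSpec(
            "bad", (LayerSpec("conv", 8, 3, 2, 1), LayerSpec("detect_head", 26, 1)), 608, 304
        )
        with pytest.raises(ValueError, match="layer 0"):
            spatial_dims(spec)

    def test_forward_shapes_agree_with_arithmetic(self, tiny_detector):
        dims = iter(spatial_dims(tiny_detector.spec))
        x = np.zeros((1, 3, 208, 208), np.float32)
        for layer_obj in tiny_detector.net.layers:
            x = layer_obj.forward(x)
            if type(layer_obj).__name__ in ("Conv2D", "MaxPool2D"):
                assert x.shape[1:] == next(dims)


class TestPrelu:
    @pytest.mark.parametrize("x,alpha,expected", [(2.0, 0.1, 2.0), (-1.0, 0.1, -0.1), (0.0, 0.1, 0.0)])
    def test_values(self, x, alpha, expected):
        assert prelu(np.array(x), alpha) == pytest.approx(expected)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            prelu(np.zeros(1), alpha=1.5)


class TestBuild:
    def test_output_tensor_shape(self, tiny_detector):
        x = np.zeros((2, 3, 208, 208), np.float32)
        out = tiny_detector.forward(x)
        assert out.shape == (2, 26, 13, 13)  # C + B*5 = 26 channels

    def test_same_seed_identical_outputs(self):
        spec = micro_spec()
        a, b = build(spec, seed=5), build(spec, seed=5)
        x = np.random.default_rng(0).normal(size=(1, 3, 16, 16)).astype(np.float32)
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_wrong_input_size_rejected(self, tiny_detector):
        with pytest.raises(ValueError):
            tiny_detector.forward(np.zeros((1, 3, 100, 100), np.float32))

    def test_anchor_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build(tiny_spec(), anchors=AnchorSet(((1.0, 1.0),)))

    def test_checkpoint_round_trip(self, tmp_path, tiny_detector):
        path = tmp_path / "w.npz"
        save_checkpoint(tiny_detector, path)
        again = load_checkpoint(path)
        x = np.random.default_rng(1).normal(size=(1, 3, 208, 208)).astype(np.float32)
        assert np.array_equal(tiny_detector.forward(x), again.forward(x))


class TestLoss:
    def perfect_raw(self, spec, anchors, truths):
        """Raw tensor exactly encoding the truths with saturated logits."""
        S, B = spec.grid_size, spec.num_anchors
        cell = spec.input_size / S
        raw = np.zeros((1, spec.output_depth, S, S), np.float32)
        anchor_part = raw[:, : B * 5].reshape(1, B, 5, S, S)
        anchor_part[0, :, 4] = -500.0  # objectness 0 everywhere
        raw[:, B * 5 :] = 500.0  # class score 1 (only read at object cells)
        for b in truths:
            cx, cy = b.center
            col, row = int(cx // cell), int(cy // cell)
            w, h = b.width / cell, b.height / cell
            ious = []
            for pw, ph in anchors.priors:
                inter = min(pw, w) * min(ph, h)
                ious.append(inter / (pw * ph + w * h - inter))
            a = int(np.argmax(ious))
            tx = cx / cell - col
            anchor_part[0, a, 0, row, col] = np.log(tx / (1 - tx))
            ty = cy / cell - row
            anchor_part[0, a, 1, row, col] = np.log(ty / (1 - ty))
            anchor_part[0, a, 2, row, col] = np.log(w / anchors.priors[a][0])
            anchor_part[0, a, 3, row, col] = np.log(h / anchors.priors[a][1])
            anchor_part[0, a, 4, row, col] = 500.0
        return raw

    def test_perfect_prediction_zero_loss(self):
        spec = tiny_spec()
        anchors = AnchorSet()
        truths = [Box(50, 50, 70, 70), Box(120, 130, 140, 155)]
        raw = self.perfect_raw(spec, anchors, truths)
        value, grad = loss(raw, [truths], anchors, spec)
        # saturated logits encode the truths exactly up to float32 rounding
        assert value == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(grad, 0.0, atol=1e-5)

    def test_single_cell_hand_computation(self):
        # 1x1 grid, one anchor slot responsible; hand-sum the three terms.
        spec = NetworkSpec(
            "one", (LayerSpec("detect_head", 6, 1),), input_size=16, grid_size=16, classes=1, num_anchors=1
        )
        # use a 1-cell logical grid by overriding grid_size in the math only
        spec = NetworkSpec("one", spec.layers, 16, 1, 1, 1)
        anchors = AnchorSet(((1.0, 1.0),))
        truth = Box(4, 4, 12, 12)  # center (8,8) = cell center; w = h = 0.5 cells
        raw = np.zeros((1, 6, 1, 1), np.float32)  # all logits zero
        value, _ = loss(raw, [[truth]], anchors, spec, LossWeights(5, 1, 0.5, 1))
        sig0 = 0.5
        coord = 5 * ((sig0 - 0.5) ** 2 * 2 + 2 * np.log(0.5) ** 2)
        obj = 1 * (sig0 - 1) ** 2
        cls = 1 * (sig0 - 1) ** 2
        assert value == pytest.approx(coord + obj + cls, rel=1e-5)

    def test_truth_outside_image_rejected(self):
        spec = tiny_spec()
        with pytest.raises(ValueError):
            loss(
                np.zeros((1, 26, 13, 13), np.float32),
                [[Box(0, 0, 300, 300)]],
                AnchorSet(),
                spec,
            )

    def test_gradient_matches_numeric_difference(self):
        spec = micro_spec()
        anchors = AnchorSet()
        truths = [[Box(2, 2, 8, 8)]]
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1, (1, 26, 4, 4)).astype(np.float64)
        value, grad = loss(raw, truths, anchors, spec)
        eps = 1e-5
        for idx in [(0, 0, 1, 1), (0, 12, 2, 0), (0, 24, 0, 2), (0, 25, 3, 3)]:
            plus = raw.copy()
            plus[idx] += eps
            minus = raw.copy()
            minus[idx] -= eps
            num = (loss(plus, truths, anchors, spec)[0] - loss(minus, truths, anchors, spec)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_loss_decreases_over_gradient_steps(self):
        spec = micro_spec()
        det = build(spec, seed=1)
        scene_cfg = cpu_scene_config(seed=0)
        img = generate_scene(scene_cfg, seed=0).image[:16, :16]
        a = AnnotatedImage(img, [Box(3, 3, 11, 11)])
        from fruitshot import nn

        x = Detector.preprocess(a.image)
        opt = nn.Adam(det.net.params(), lr=0.01)
        values = []
        for _ in range(50):
            raw = det.forward(x, train=True)
            v, g = loss(raw, [a.boxes], det.anchors, det.spec)
            det.net.zero_grad()
            det.net.backward(g)
            opt.step()
            values.append(v)
        assert values[-1] < values[0] * 0.5
        assert values[-1] == min(values)


class TestTrain:
    def make_data(self, n, seed0=0):
        cfg = cpu_scene_config()
        return [generate_scene(cfg, seed=seed0 + i) for i in range(n)]

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)

    def test_empty_dataset_rejected(self, tiny_detector):
        with pytest.raises(ValueError):
            train(tiny_detector, [], TrainConfig(epochs=1, steps=1))

    def test_wrong_image_size_rejected(self, tiny_detector):
        bad = AnnotatedImage(np.zeros((100, 100, 3), np.uint8), [])
        with pytest.raises(ValueError):
            train(tiny_detector, [bad], TrainConfig(epochs=1, steps=1))

    def test_frozen_backbone_weights_unchanged(self):
        det = build(tiny_spec(), seed=2)
        data = self.make_data(4)
        before = [l.W.copy() for l in det.net.layers if hasattr(l, "W")]
        cfg = TrainConfig(epochs=1, steps=3, batch_size=2, freeze_backbone=True, seed=0)
        train(det, data, cfg)
        convs = [l for l in det.net.layers if hasattr(l, "W")]
        for w0, conv in zip(before[:-1], convs[:-1]):
            assert np.array_equal(w0, conv.W)
        assert not np.array_equal(before[-1], convs[-1].W)  # head did train

    def test_training_reproducible_with_seed(self):
        data = self.make_data(4)
        cfg = TrainConfig(epochs=2, steps=3, batch_size=2, seed=7)
        log1 = train(build(tiny_spec(), seed=3), data, cfg)
        log2 = train(build(tiny_spec(), seed=3), data, cfg)
        assert log1 == log2


class TestPredict:
    def test_all_zero_logits_below_threshold(self, tiny_detector):
        # sigma(0)=0.5 objectness * 0.5 class = 0.25 < 0.6 threshold
        det = build(tiny_spec(), seed=0)
        for conv in [l for l in det.net.layers if hasattr(l, "W")]:
            conv.W[...] = 0
            conv.b[...] = 0
        img = np.zeros((208, 208, 3), np.uint8)
        assert len(det.predict(img, conf_threshold=0.6)) == 0

    def test_threshold_zero_nms_off_gives_all_slots(self):
        det = build(tiny_spec(), seed=0)
        for conv in [l for l in det.net.layers if hasattr(l, "W")]:
            conv.W[...] = 0
            conv.b[...] = 0
        img = np.zeros((208, 208, 3), np.uint8)
        dets = det.predict(img, conf_threshold=0.0, nms_threshold=None)
        assert len(dets) == 13 * 13 * 5

    def test_inference_deterministic(self, tiny_detector, small_scene):
        a = tiny_detector.predict(small_scene.image, conf_threshold=0.1)
        b = tiny_detector.predict(small_scene.image, conf_threshold=0.1)
        assert a.boxes == b.boxes
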