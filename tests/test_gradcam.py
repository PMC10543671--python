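"""Grad-CAM machinery: gradients, importance weights, maps, guided variant."""

import numpy as np
import pytest
from conftest import make_model

import braggcam as bc
from braggcam.gradcam import (
    activation_histogram,
    gradcam,
    guided_backprop,
    guided_gradcam,
    localization_score,
    neuron_importance,
    overlay_heatmap,
    score_gradients,
)
from braggcam.nn import Conv2D, Dense, Flatten, GlobalAvgPool, MaxPool2D, Network, ReLU


def tiny_convnet(seed=0, size=8, n_classes=2):
    """Fixed-weight conv-ReLU-pool-flatten-dense network (float64)."""
    rng = np.random.default_rng(seed)
    conv = Conv2D(1, 3, 3, stride=1, rng=rng)
    pool = MaxPool2D(2)
    dense = Dense(3 * (size // 2) ** 2, n_classes, rng=rng)
    net = Network([conv, ReLU(), pool, Flatten(), dense], {"conv1": 1, "fc1": 4})
    return make_model(net, size, n_classes)


def gap_head_net(seed=1, size=8, K=4, n_classes=3):
    """conv -> ReLU -> GAP -> linear head; the classic CAM architecture."""
    rng = np.random.default_rng(seed)
    conv = Conv2D(1, K, 3, stride=1, rng=rng)
    head = Dense(K, n_classes, rng=rng)
    net = Network([conv, ReLU(), GlobalAvgPool(), head], {"conv1": 1, "head": 3})
    return make_model(net, size, n_classes)


class TestScoreGradients:
    def test_gap_identity_head_gives_uniform_gradient(self):
        # y^c = GAP of a single map followed by an identity pick-off
        conv = Conv2D(1, 1, 1, pad=0)
        conv.params["W"][:] = 1.0
        conv.params["b"][:] = 0.0
        head = Dense(1, 2)
        head.params["W"][:] = np.array([[1.0, 0.0]])
        head.params["b"][:] = 0.0
        net = Network([conv, GlobalAvgPool(), head], {"conv1": 0, "head": 2})
        model = make_model(net, 6, 2)
        g = score_gradients(model, np.random.default_rng(0).random((6, 6)), 0, "conv1")
        np.testing.assert_allclose(g, np.full((1, 6, 6), 1.0 / 36.0))

    def test_matches_central_finite_differences(self):
        model = tiny_convnet()
        # keep all activations strictly positive so the pooling argmax has no
        # ties and the loss is smooth at the probe points
        model.net.layers[0].params["b"][:] = 3.0
        frame = np.random.default_rng(3).random((8, 8))
        x = model.preprocess(frame)
        c = 1
        got = score_gradients(model, frame, c, "conv1")

        def score_from_acts(acts):
            h = acts
            for layer in model.net.layers[2:]:
                h, _ = layer.forward(h)
            return float(h[0, c])

        acts = model.net.activations(x, "conv1").copy()
        eps = 1e-5
        rng = np.random.default_rng(7)
        flat = rng.choice(acts.size, size=25, replace=False)
        for fi in flat:
            idx = np.unravel_index(fi, acts.shape)  # (batch, K, h, w)
            a = acts.copy()
            a[idx] += eps
            fp = score_from_acts(a)
            a[idx] -= 2 * eps
            fm = score_from_acts(a)
            num = (fp - fm) / (2 * eps)
            analytic = got[idx[1:]]
            denom = max(abs(num), abs(analytic), 1e-8)
            assert abs(analytic - num) / denom < 1e-4

    def test_gradient_is_zero_without_a_path_to_the_class(self):
        # block-diagonal head: maps 0..1 feed class 0, maps 2..3 feed class 1
        rng = np.random.default_rng(2)
        conv = Conv2D(1, 4, 3, rng=rng)
        head = Dense(4, 2)
        head.params["W"][:] = 0.0
        head.params["W"][0:2, 0] = 1.0
        head.params["W"][2:4, 1] = 1.0
        net = Network([conv, ReLU(), GlobalAvgPool(), head], {"conv1": 1, "head": 3})
        model = make_model(net, 8, 2)
        g = score_gradients(model, rng.random((8, 8)), 0, "conv1")
        assert np.all(g[2:] == 0)

    def test_unknown_layer_rejected(self):
        model = tiny_convnet()
        with pytest.raises(KeyError):
            score_gradients(model, np.zeros((8, 8)), 0, "conv7")


class TestNeuronImportance:
    def test_arithmetic_mean_examples(self):
        assert neuron_importance(np.array([[[1.0, 2.0], [3.0, 4.0]]]))[0] == 2.5
        assert np.all(neuron_importance(np.ones((3, 4, 5))) == 1.0)

    def test_matches_double_sum_oracle(self):
        g = np.random.default_rng(4).standard_normal((6, 5, 7))
        alpha = neuron_importance(g)
        for k in range(6):
            total = 0.0
            for i in range(5):
                for j in range(7):
                    total += g[k, i, j]
            assert alpha[k] == pytest.approx(total / 35.0)


class TestGradCam:
    def test_raw_map_is_relu_of_importance_weighted_sum(self):
        model = tiny_convnet(seed=5)
        frame = np.random.default_rng(6).random((8, 8))
        res = gradcam(model, frame, class_index=0, layer="conv1")
        acts = model.activations(frame, "conv1")
        grads = score_gradients(model, frame, 0, "conv1")
        alpha = grads.mean(axis=(1, 2))
        expected = np.maximum(sum(a * A for a, A in zip(alpha, acts)), 0.0)
        np.testing.assert_allclose(res.raw_map, expected, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(res.importance, alpha)

    def test_weighted_sum_cancellation_gives_zero_map(self):
        A = np.array([[[1.0, -1.0], [0.0, 2.0]], [[1.0, -1.0], [0.0, 2.0]]])
        alpha = np.array([1.0, -1.0])
        raw = np.maximum(np.tensordot(alpha, A, axes=1), 0.0)
        assert np.all(raw == 0.0)
        single = np.maximum(np.tensordot(np.array([1.0]), A[:1], axes=1), 0.0)
        assert single.tolist() == [[1.0, 0.0], [0.0, 2.0]]

    def test_heatmap_normalized_and_input_sized(self):
        model = tiny_convnet(seed=8)
        frame = np.random.default_rng(9).random((8, 8))
        res = gradcam(model, frame, layer="conv1")
        assert res.heatmap.shape == (8, 8)
        assert res.heatmap.min() >= 0.0 and res.heatmap.max() <= 1.0
        assert res.raw_map.min() >= 0.0

    def test_all_zero_map_stays_all_zero(self):
        model = tiny_convnet(seed=10)
        for name in ("W", "b"):
            model.net.layers[0].params[name][:] = 0.0
        res = gradcam(model, np.random.default_rng(1).random((8, 8)),
                      class_index=0, layer="conv1")
        assert np.all(res.heatmap == 0.0)

    def test_equals_cam_on_gap_head_network(self):
        model = gap_head_net()
        frame = np.random.default_rng(11).random((8, 8))
        for c in range(3):
            res = gradcam(model, frame, class_index=c, layer="conv1")
            acts = model.activations(frame, "conv1")
            w = model.net.layers[-1].params["W"][:, c]
            cam = np.maximum(np.tensordot(w, acts, axes=1), 0.0)
            hw = acts.shape[1] * acts.shape[2]
            np.testing.assert_allclose(res.raw_map * hw, cam, rtol=1e-9, atol=1e-12)


class TestGuided:
    def test_relu_guided_masks(self):
        relu = ReLU()
        _, mask = relu.forward(np.array([[-1.0]]))
        assert relu.backward(np.array([[5.0]]), mask, guided=True) == 0.0
        _, mask = relu.forward(np.array([[1.0]]))
        assert relu.backward(np.array([[-2.0]]), mask, guided=True) == 0.0
        assert relu.backward(np.array([[2.0]]), mask, guided=True) == 2.0

    def test_guided_equals_plain_when_everything_is_positive(self):
        rng = np.random.default_rng(12)
        conv = Conv2D(1, 2, 3, rng=rng)
        conv.params["W"][:] = np.abs(conv.params["W"])
        conv.params["b"][:] = 0.1
        head = Dense(2, 2)
        head.params["W"][:] = np.abs(np.random.default_rng(13).standard_normal((2, 2)))
        net = Network([conv, ReLU(), GlobalAvgPool(), head], {"conv1": 1, "head": 3})
        model = make_model(net, 8, 2)
        frame = np.abs(rng.random((8, 8))) + 1.0

        guided = guided_backprop(model, frame, class_index=0)
        x = model.preprocess(frame)
        logits, _, caches = model.net.forward(x, want_caches=True)
        seed = np.zeros_like(logits)
        seed[0, 0] = 1.0
        plain, _ = model.net.backward(seed, caches, guided=False)
        np.testing.assert_allclose(guided.grad, plain[0].mean(axis=0))

    def test_guided_gradcam_product(self):
        model = tiny_convnet(seed=14)
        frame = np.random.default_rng(15).random((8, 8))
        res = gradcam(model, frame, class_index=0, layer="conv1")
        guided = guided_backprop(model, frame, class_index=0)
        out = guided_gradcam(res, guided)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == res.heatmap[i, j] * guided.grad[i, j]
        res.heatmap = np.zeros_like(res.heatmap)
        assert np.all(guided_gradcam(res, guided) == 0.0)
        res.heatmap = np.ones_like(res.heatmap)
        np.testing.assert_array_equal(guided_gradcam(res, guided), guided.grad)
        res.heatmap = res.heatmap[:4, :4]
        with pytest.raises(ValueError):
            guided_gradcam(res, guided)


class TestHistogramAndLocalization:
    def test_constant_array_occupies_single_bin(self):
        edges, counts = activation_histogram(np.full((10, 10), 3.0), n_bins=7)
        assert counts.sum() == 100
        assert (counts > 0).sum() == 1

    def test_histogram_matches_brute_force_binning(self):
        values = np.random.default_rng(16).random(500)
        edges, counts = activation_histogram(values, n_bins=10)
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            expected = sum(
                1 for v in values if (lo <= v < hi) or (b == 9 and v == hi)
            )
            assert counts[b] == expected

    def test_localization_score_examples(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        heat = np.zeros((10, 10))
        heat[3, 3] = 5.0
        assert localization_score(heat, mask) == 1.0
        uniform = np.ones((10, 10))
        assert localization_score(uniform, mask) == pytest.approx(mask.mean())
        rng = np.random.default_rng(17)
        h = rng.random((10, 10))
        assert localization_score(h, mask) == pytest.approx(h[mask].sum() / h.sum())
        with pytest.raises(ValueError):
            localization_score(np.zeros((10, 10)), mask)

    def test_overlay_is_rgb_in_unit_range(self):
        frame = np.random.default_rng(18).random((8, 8))
        heat = np.random.default_rng(19).random((8, 8))
        rgb = overlay_heatmap(frame, heat)
        assert rgb.shape == (8, 8, 3)
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0
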