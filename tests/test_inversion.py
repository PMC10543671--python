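"""Representation inversion: objective components, optimizer behaviour."""

import numpy as np
import pytest

import braggcam as bc
from braggcam.inversion import (
    InversionConfig,
    alpha_norm_prior,
    invert,
    invert_per_layer,
    rep_distance,
    representation,
    sigma_from_frames,
    tv_prior,
)


@pytest.fixture(scope="module")
def small_model():
    return bc.build_model(bc.desk_alexnet_spec(input_size=16), seed=0, dtype=np.float64)


class TestRepDistance:
    def test_identity_of_representations_is_zero(self, small_model):
        x = np.random.default_rng(0).standard_normal((1, 16, 16))
        phi0 = representation(small_model, x, "conv1")
        assert rep_distance(small_model, x, phi0, "conv1") == 0.0

    def test_doubling_gives_unit_normalized_distance(self, small_model):
        x = np.random.default_rng(1).standard_normal((1, 16, 16))
        phi0 = representation(small_model, x, "input")
        assert rep_distance(small_model, 2 * x, phi0, "input") == pytest.approx(1.0)

    def test_matches_loop_based_sum_of_squares(self, small_model):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 16, 16))
        phi0 = representation(small_model, x, "conv2") + rng.standard_normal(
            representation(small_model, x, "conv2").shape
        )
        phi = representation(small_model, x, "conv2")
        total = 0.0
        for a, b in zip(phi.ravel(), phi0.ravel()):
            total += (a - b) ** 2
        expected = total / (phi0**2).sum()
        assert rep_distance(small_model, x, phi0, "conv2") == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, small_model):
        x = np.random.default_rng(3).standard_normal((1, 16, 16))
        with pytest.raises(ValueError):
            rep_distance(small_model, x, np.zeros((2, 3, 3)), "conv1")


class TestPriors:
    def test_alpha_norm_closed_forms(self):
        # mean subtraction annihilates a constant image (up to float residue)
        assert alpha_norm_prior(np.full((5, 5), 3.7), 6.0) == pytest.approx(0.0, abs=1e-12)
        assert alpha_norm_prior(np.full((5, 5), 2.0), 6.0) == 0.0
        assert alpha_norm_prior(np.array([1.0, -1.0]), 6.0) == pytest.approx(2.0)

    def test_alpha_norm_matches_loop_oracle(self):
        x = np.random.default_rng(4).standard_normal((7, 7))
        a = 6.0
        mean = x.mean()
        expected = sum(abs(v - mean) ** a for v in x.ravel())
        assert alpha_norm_prior(x, a) == pytest.approx(expected)

    def test_tv_closed_forms(self):
        assert tv_prior(np.full((4, 4), 2.0), 1.0) == 0.0
        # two horizontal unit steps, no vertical steps
        assert tv_prior(np.array([[0.0, 1.0], [0.0, 1.0]]), 1.0) == pytest.approx(2.0)

    def test_tv_beta_two_is_sum_of_squared_differences(self):
        x = np.random.default_rng(5).standard_normal((6, 6))
        expected = 0.0
        for i in range(6):
            for j in range(6):
                dj = x[i, j + 1] - x[i, j] if j + 1 < 6 else 0.0
                di = x[i + 1, j] - x[i, j] if i + 1 < 6 else 0.0
                expected += dj**2 + di**2
        assert tv_prior(x, 2.0) == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_tv_gradient_matches_finite_differences(self, beta):
        from braggcam.inversion import _tv_grad

        x = np.random.default_rng(6).standard_normal((5, 5))
        g = _tv_grad(x, beta)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4), (1, 1)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (tv_prior(xp, beta) - tv_prior(xm, beta)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_alpha_gradient_matches_finite_differences(self):
        from braggcam.inversion import _alpha_norm_grad

        x = np.random.default_rng(7).standard_normal((5, 5))
        g = _alpha_norm_grad(x, 6.0)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (4, 4)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (alpha_norm_prior(xp, 6.0) - alpha_norm_prior(xm, 6.0)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestInvert:
    def test_identity_layer_recovers_original(self, small_model):
        x0 = np.random.default_rng(3).standard_normal((1, 16, 16))
        cfg = InversionConfig(layer="input", lambda_alpha=0.0, lambda_tv=0.0,
                              sigma=1.0, iterations=300, seed=4)
        res = invert(small_model, x0, cfg)
        assert res.final_rep_distance < 1e-3
        span = x0.max() - x0.min()
        assert np.abs(res.x_star - x0).max() < 0.05 * span

    def test_deterministic_given_seed(self, small_model):
        x0 = np.random.default_rng(8).standard_normal((1, 16, 16))
        phi0 = representation(small_model, x0, "conv1")
        cfg = InversionConfig(layer="conv1", iterations=40, seed=9)
        a = invert(small_model, phi0, cfg)
        b = invert(small_model, phi0, cfg)
        assert np.array_equal(a.x_star, b.x_star)
        assert a.loss_trace == b.loss_trace

    def test_trace_components_non_negative_and_consistent(self, small_model):
        x0 = np.random.default_rng(10).standard_normal((1, 16, 16))
        phi0 = representation(small_model, x0, "conv2")
        cfg = InversionConfig(layer="conv2", iterations=30, seed=11,
                              lambda_alpha=1e-5, lambda_tv=1e-3)
        res = invert(small_model, phi0, cfg)
        for entry in res.loss_trace:
            assert entry["rep_distance"] >= 0
            assert entry["alpha_norm"] >= 0
            assert entry["tv"] >= 0
            total = (
                entry["rep_distance"]
                + cfg.lambda_alpha * entry["alpha_norm"]
                + cfg.lambda_tv * entry["tv"]
            )
            assert entry["total"] == pytest.approx(total)
        best = min(e["total"] for e in res.loss_trace)
        best_entry = next(e for e in res.loss_trace if e["total"] == best)
        assert res.final_rep_distance == best_entry["rep_distance"]

    def test_stronger_tv_weight_yields_smoother_reconstructions(self, small_model):
        x0 = bc.simulate_frame(
            bc.default_scene_params("Strong", image_size=16, seed=12,
                                    peak_sigma=1.0, n_peaks_range=(2, 2))
        ).pixels.astype(float)
        x0 = (x0 - x0.mean()) / (x0.std() + 1e-8)
        tvs = []
        for lam in (1e-4, 1e-2, 1.0):
            cfg = InversionConfig(layer="input", lambda_alpha=0.0, lambda_tv=lam,
                                  sigma=1.0, iterations=150, seed=13)
            res = invert(small_model, x0[None], cfg)
            tvs.append(tv_prior(res.x_star.mean(axis=0), 1.0))
        assert tvs[0] > tvs[1] > tvs[2]

    def test_non_finite_objective_aborts_naming_component(self, small_model):
        phi0 = np.full((1, 16, 16), np.inf)
        cfg = InversionConfig(layer="input", iterations=5, seed=0)
        with pytest.raises(FloatingPointError, match="representation distance"):
            invert(small_model, phi0, cfg)


class TestInvertPerLayer:
    def test_single_layer_gives_single_result(self, small_model):
        frame = bc.simulate_frame(
            bc.default_scene_params("Good", image_size=16, seed=14,
                                    peak_sigma=1.0, n_peaks_range=(2, 3))
        )
        cfg = InversionConfig(iterations=20, seed=15)
        results = invert_per_layer(small_model, frame, ["conv1"], cfg)
        assert len(results) == 1 and results[0].layer == "conv1"

    def test_shared_seed_reproducible_panel(self, small_model):
        frame = bc.simulate_frame(
            bc.default_scene_params("Weak", image_size=16, seed=16,
                                    peak_sigma=1.0, n_peaks_range=(2, 3))
        )
        cfg = InversionConfig(iterations=15, seed=17)
        a = invert_per_layer(small_model, frame, ["conv1", "conv2"], cfg)
        b = invert_per_layer(small_model, frame, ["conv1", "conv2"], cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.x_star, rb.x_star)


def test_sigma_is_mean_euclidean_norm_of_standardized_frames(small_model):
    frames = [
        bc.simulate_frame(
            bc.default_scene_params("Good", image_size=16, seed=s,
                                    peak_sigma=1.0, n_peaks_range=(2, 3))
        )
        for s in range(3)
    ]
    sigma = sigma_from_frames(small_model, frames)
    x = small_model.preprocess(frames)
    expected = np.mean([np.linalg.norm(xi.ravel()) for xi in x])
    assert sigma == pytest.approx(expected)
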