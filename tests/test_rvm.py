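"""Weighted kernel and sparse Bayesian classifier contracts."""

import math

import numpy as np
import pytest

from tomatoseg.rvm import (
    RvmModel,
    classify_block,
    predict_prob,
    second_layer_mask,
    train_rvm,
    weighted_kernel,
)


def _two_blobs(seed=42, n=200, means=(0.2, 0.8), sd=0.05, d=2):
    rng = np.random.default_rng(seed)
    A = rng.normal(means[0], sd, (n, d))
    B = rng.normal(means[1], sd, (n, d))
    X = np.clip(np.vstack([A, B]), 0, 1)
    y = np.array([0] * n + [1] * n)  # 0 = target
    return X, y


@pytest.fixture(scope="module")
def blob_model():
    X, y = _two_blobs()
    model = train_rvm(X, y, np.full(2, 0.5))
    return X, y, model


class TestWeightedKernel:
    def test_identical_inputs_give_one(self, rng):
        x = rng.random(11)
        assert weighted_kernel(x, x, rng.random(11)) == pytest.approx(1.0)

    def test_zero_weights_gate_the_metric(self):
        x = np.zeros(11)
        y = np.ones(11)
        w = np.zeros(11)
        assert weighted_kernel(x, y, w) == pytest.approx(1.0)

    def test_direct_sum_oracle(self, rng):
        for _ in range(20):
            x, y = rng.random(11), rng.random(11)
            w = rng.random(11)
            width = rng.uniform(0.1, 2.0)
            expected = math.exp(
                -sum(w[j] * (x[j] - y[j]) ** 2 for j in range(11)) / (2 * width**2)
            )
            assert abs(weighted_kernel(x, y, w, width) - expected) < 1e-12

    def test_uniform_weights_reduce_to_plain_rbf(self, rng):
        x, y = rng.random(11), rng.random(11)
        w = np.full(11, 1.0 / 11)
        width = 0.5
        rbf = math.exp(-np.sum((x - y) ** 2) / 11 / (2 * width**2))
        assert abs(weighted_kernel(x, y, w, width) - rbf) < 1e-12

    def test_gram_matrix_symmetric_psd(self, rng):
        X = rng.random((40, 11))
        w = rng.random(11)
        w /= w.sum()
        K = weighted_kernel(X, X, w)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(K)
        assert eigvals.min() > -1e-9

    def test_nonpositive_width_rejected(self, rng):
        with pytest.raises(ValueError):
            weighted_kernel(rng.random(3), rng.random(3), np.ones(3), width=0.0)


class TestTraining:
    def test_separable_blobs_high_accuracy_and_sparse(self, blob_model):
        X, y, model = blob_model
        p = predict_prob(model, X, normalized=True)
        acc = np.mean((p > 0.5) == (y == 0))
        assert acc >= 0.98
        assert len(model.relevance_vectors) <= 0.2 * len(y)
        assert len(model.relevance_vectors) < len(y)

    def test_label_swap_flips_probabilities(self, blob_model):
        X, y, model = blob_model
        swapped = train_rvm(X, 1 - y, np.full(2, 0.5))
        p = predict_prob(model, X, normalized=True)
        q = predict_prob(swapped, X, normalized=True)
        assert np.abs(p - (1 - q)).max() < 1e-6

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError):
            train_rvm(X, np.zeros(10, int), np.full(2, 0.5))

    def test_identical_features_rejected(self):
        X = np.ones((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError):
            train_rvm(X, y, np.full(2, 0.5))

    def test_training_is_deterministic(self):
        X, y = _two_blobs(seed=9, n=60)
        m1 = train_rvm(X, y, np.full(2, 0.5))
        m2 = train_rvm(X, y, np.full(2, 0.5))
        np.testing.assert_array_equal(m1.mu, m2.mu)
        np.testing.assert_array_equal(m1.relevance_vectors, m2.relevance_vectors)


class TestPrediction:
    def test_probabilities_lie_in_unit_interval_on_grid(self, blob_model):
        _, _, model = blob_model
        g = np.linspace(0, 1, 25)
        grid = np.array([(a, b) for a in g for b in g])
        p = predict_prob(model, grid, normalized=True)
        assert (p >= 0).all() and (p <= 1).all()

    def test_monotone_along_discriminant_direction(self, blob_model):
        _, _, model = blob_model
        ts = np.linspace(0, 1, 50)
        line = np.column_stack([ts, ts])  # from target blob to non-target blob
        p = predict_prob(model, line, normalized=True)
        assert (np.diff(p) <= 1e-9).all()

    def test_confident_target_point_above_half(self, blob_model):
        X, y, model = blob_model
        assert predict_prob(model, X[0], normalized=True) > 0.5

    def test_strict_half_rule(self, blob_model):
        _, _, model = blob_model
        # the rule itself: exactly 0.5 is non-target
        assert classify_block(model, np.array([[0.5, 0.5]]), normalized=True).dtype == bool
        p = 0.5
        assert not (p > 0.5)

    def test_decisions_agree_with_thresholded_probabilities(self, blob_model, rng):
        _, _, model = blob_model
        X = rng.random((1000, 2))
        p = predict_prob(model, X, normalized=True)
        d = classify_block(model, X, normalized=True)
        np.testing.assert_array_equal(d, p > 0.5)

    def test_wrong_dimensionality_rejected(self, blob_model):
        _, _, model = blob_model
        with pytest.raises(ValueError):
            predict_prob(model, np.zeros(5), normalized=True)

    def test_non_finite_features_replaced_not_crashing(self, blob_model):
        _, _, model = blob_model
        x = np.array([np.nan, np.inf])
        p = predict_prob(model, x)
        assert 0.0 <= p <= 1.0


class TestSerialization:
    def test_round_trip_preserves_predictions(self, blob_model, tmp_path, rng):
        _, _, model = blob_model
        path = tmp_path / "model.json"
        model.save(path)
        back = RvmModel.load(path)
        X = rng.random((50, 2))
        np.testing.assert_array_equal(
            predict_prob(model, X, normalized=True),
            predict_prob(back, X, normalized=True),
        )

    def test_checksum_stable_across_saves(self, blob_model, tmp_path):
        _, _, model = blob_model
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        model.save(p1)
        model.save(p2)
        assert model.checksum(p1) == model.checksum(p2)

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(ValueError):
            RvmModel.load(path)


class TestSecondLayerMask:
    def test_mask_constant_within_blocks_and_full_size(self, trained_model, rng):
        img = rng.integers(0, 256, (27, 36, 3), dtype=np.uint8)
        mask = second_layer_mask(img, trained_model)
        assert mask.shape == (27, 36)
        from tomatoseg.imaging import tile_blocks

        for blk in tile_blocks(img):
            win = mask[blk.slice()]
            assert win.min() == win.max()

    def test_background_scene_mostly_rejected(self, trained_model):
        from tomatoseg.synthetic import SceneSpec
        import tomatoseg as ts

        scene = ts.generate_scene(SceneSpec(n_fruit=0, seed=77))
        mask = second_layer_mask(scene.image, trained_model)
        assert mask.mean() / 255 <= 0.05

    def test_fruit_blocks_recognised(self, trained_model, training_scenes):
        scene = training_scenes[0]
        mask = second_layer_mask(scene.image, trained_model)
        truth = scene.truth_mask > 0
        # most truth-fruit pixels fall in blocks classified target
        assert (mask[truth] == 255).mean() >= 0.8
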