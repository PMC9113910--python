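import numpy as np
import pytest

from alffkit.autoencoder_clf import (
    AutoencoderModel,
    LayerParams,
    SoftmaxClassifier,
    comparison_experiment,
    decode,
    encode,
    fine_features,
    finetune_with_softmax,
    reconstruction_loss,
    train_autoencoder,
    train_softmax,
)
from alffkit.autoencoder_clf import _bce_grads
from alffkit.synthetic_data import simulate_feature_table


def identity_model(dim=3):
    enc = LayerParams(np.eye(dim - 1, dim), np.zeros(dim - 1), activation="identity")
    dec = LayerParams(np.eye(dim, dim - 1), np.zeros(dim), activation="identity")
    return AutoencoderModel(encoder=[enc], decoder=[dec], input_dim=dim)


class TestEncodeDecode:
    def test_identity_weights_pass_input_through(self):
        w = np.eye(3)
        model = AutoencoderModel(
            encoder=[LayerParams(w[:2], np.zeros(2), "identity")],
            decoder=[LayerParams(w[:, :2], np.zeros(3), "identity")],
            input_dim=3,
        )
        x = np.array([0.2, 0.7, 0.1])
        np.testing.assert_allclose(encode(x, model), x[:2])

    def test_zero_weights_sigmoid_gives_half(self):
        model = AutoencoderModel(
            encoder=[LayerParams(np.zeros((2, 4)), np.zeros(2))],
            decoder=[LayerParams(np.zeros((4, 2)), np.zeros(4))],
            input_dim=4,
        )
        np.testing.assert_allclose(encode(np.full(4, 0.3), model), 0.5)
        np.testing.assert_allclose(decode(np.array([0.1, 0.9]), model), 0.5)

    def test_hand_computed_single_layer(self):
        model = AutoencoderModel(
            encoder=[LayerParams(np.array([[1.0, -1.0]]), np.zeros(1))],
            decoder=[],
            input_dim=2,
        )
        np.testing.assert_allclose(encode(np.array([1.0, 1.0]), model), [0.5])

    def test_orthonormal_linear_mirror_reconstructs_exactly(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        w = q[:3]  # 3x4 with orthonormal rows
        model = AutoencoderModel(
            encoder=[LayerParams(w, np.zeros(3), "identity")],
            decoder=[LayerParams(w.T, np.zeros(4), "identity")],
            input_dim=4,
        )
        x = w.T @ rng.random(3)  # in the row space, so W^T W x = x
        np.testing.assert_allclose(decode(encode(x, model), model), x, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        model = identity_model(3)
        with pytest.raises(ValueError, match="dimension"):
            encode(np.zeros(5), model)
        with pytest.raises(ValueError, match="dimension"):
            decode(np.zeros(5), model)

    def test_mirror_violation_rejected(self):
        with pytest.raises(ValueError, match="mirror|code"):
            AutoencoderModel(
                encoder=[LayerParams(np.zeros((2, 4)), np.zeros(2))],
                decoder=[LayerParams(np.zeros((4, 3)), np.zeros(4))],
                input_dim=4,
            )


class TestReconstructionLoss:
    def test_exact_binary_reconstruction_gives_zero(self):
        x = np.array([1.0, 0.0, 1.0])
        assert reconstruction_loss(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_two_ln_two(self):
        loss = reconstruction_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert loss == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            x = rng.random(6)
            y = np.clip(rng.random(6), 1e-6, 1 - 1e-6)
            assert reconstruction_loss(x, y) >= 0.0

    def test_gradient_wrt_y_matches_finite_differences(self, rng):
        x = rng.random(5)
        y = np.clip(rng.random(5), 0.1, 0.9)
        analytic = (y - x) / (y * (1 - y))
        h = 1e-7
        for i in range(5):
            yp, ym = y.copy(), y.copy()
            yp[i] += h
            ym[i] -= h
            fd = (reconstruction_loss(x, yp) - reconstruction_loss(x, ym)) / (2 * h)
            assert fd == pytest.approx(analytic[i], rel=1e-5, abs=1e-6)

    def test_out_of_domain_x_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.array([1.5]), np.array([0.5]))


class TestBackpropGradients:
    def test_full_model_gradients_match_finite_differences(self, rng):
        layers = [
            LayerParams(rng.uniform(-0.5, 0.5, (3, 4)), rng.uniform(-0.1, 0.1, 3)),
            LayerParams(rng.uniform(-0.5, 0.5, (2, 3)), rng.uniform(-0.1, 0.1, 2)),
            LayerParams(rng.uniform(-0.5, 0.5, (3, 2)), rng.uniform(-0.1, 0.1, 3)),
            LayerParams(rng.uniform(-0.5, 0.5, (4, 3)), rng.uniform(-0.1, 0.1, 4)),
        ]
        x = rng.random((6, 4))
        _, grads = _bce_grads(layers, x, x)
        h = 1e-6
        for li, layer in enumerate(layers):
            for index in [(0, 0), (layer.weights.shape[0] - 1, layer.weights.shape[1] - 1)]:
                orig = layer.weights[index]
                layer.weights[index] = orig + h
                lp, _ = _bce_grads(layers, x, x)
                layer.weights[index] = orig - h
                lm, _ = _bce_grads(layers, x, x)
                layer.weights[index] = orig
                fd = (lp - lm) / (2 * h)
                assert fd == pytest.approx(grads[li][0][index], rel=1e-5, abs=1e-7)
            orig = layer.bias[0]
            layer.bias[0] = orig + h
            lp, _ = _bce_grads(layers, x, x)
            layer.bias[0] = orig - h
            lm, _ = _bce_grads(layers, x, x)
            layer.bias[0] = orig
            fd = (lp - lm) / (2 * h)
            assert fd == pytest.approx(grads[li][1][0], rel=1e-5, abs=1e-7)


class TestTrainAutoencoder:
    def test_loss_history_nonincreasing_and_improves(self, rng):
        x = rng.random((40, 8))
        model = train_autoencoder(x, epochs=60, seed=0)
        h = np.array(model.history)
        assert np.all(np.diff(h) <= 1e-12)
        assert h[-1] < h[0]

    def test_identical_rows_approach_entropy_floor(self):
        row = np.array([0.2, 0.8, 0.5, 0.9])
        x = np.tile(row, (30, 1))
        model = train_autoencoder(x, layer_dims=[3, 2], epochs=400, seed=1)
        floor = -np.sum(row * np.log(row) + (1 - row) * np.log(1 - row))
        assert model.history[-1] >= floor - 1e-9
        assert model.history[-1] < floor + 0.1

    def test_same_seed_identical_weights(self, rng):
        x = rng.random((30, 6))
        m1 = train_autoencoder(x, epochs=30, seed=7)
        m2 = train_autoencoder(x, epochs=30, seed=7)
        for l1, l2 in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(l1.weights, l2.weights)
            np.testing.assert_array_equal(l1.bias, l2.bias)

    def test_out_of_domain_data_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_autoencoder(np.full((5, 4), 2.0), epochs=1)

    def test_nondecreasing_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="decreasing"):
            train_autoencoder(rng.random((10, 4)), layer_dims=[4, 2], epochs=1)

    def test_reconstruction_beats_untrained_baseline(self, rng):
        x = rng.random((50, 6))
        trained = train_autoencoder(x, epochs=150, seed=3)
        recon = decode(encode(x, trained), trained)
        # history[0] is the loss of the pretrained-but-not-finetuned stack
        assert reconstruction_loss(x, recon) < trained.history[0]


class TestFineFeatures:
    def test_shape_and_determinism(self, rng):
        x = rng.random((25, 8))
        model = train_autoencoder(x, epochs=20, seed=0)
        f = fine_features(x, model)
        assert f.shape == (25, model.code_dim)
        np.testing.assert_array_equal(f, fine_features(x, model))

    def test_differs_from_raw_features(self, rng):
        x = rng.random((25, 8))
        model = train_autoencoder(x, epochs=20, seed=0)
        assert fine_features(x, model).shape[1] != x.shape[1]


class TestSoftmax:
    def test_separable_blobs_high_heldout_accuracy(self):
        x, y = simulate_feature_table(80, 6, structure="linear", seed=0, class_sep=5.0)
        _, acc = train_softmax(x, y, seed=0)
        assert acc >= 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            SoftmaxClassifier().fit(rng.random((10, 3)), np.zeros(10))

    def test_probabilities_sum_to_one(self, rng):
        x = rng.random((30, 4))
        y = rng.integers(0, 3, size=30)
        clf = SoftmaxClassifier().fit(x, y, epochs=50)
        p = clf.predict_proba(rng.random((12, 4)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_loss_history_nonincreasing(self, rng):
        x = rng.random((40, 5))
        y = rng.integers(0, 2, size=40)
        clf = SoftmaxClassifier().fit(x, y, epochs=80)
        assert np.all(np.diff(clf.history) <= 1e-12)


class TestComparisonExperiment:
    def test_linear_structure_saturates_both_feature_sets(self):
        x, y = simulate_feature_table(60, 8, structure="linear", seed=0, class_sep=6.0)
        report = comparison_experiment(
            x, y, seeds=range(2), layer_dims=[6, 4, 2], finetune_epochs=1500
        )
        means = report.groupby("features")["accuracy"].mean()
        assert means["raw"] >= 0.95
        assert means["fine"] >= 0.95

    def test_permuted_labels_give_chance_accuracy(self, rng):
        x, y = simulate_feature_table(60, 8, structure="linear", seed=0, class_sep=6.0)
        y_perm = rng.permutation(y)
        report = comparison_experiment(
            x, y_perm, seeds=range(3), layer_dims=[6, 4, 2], finetune_epochs=500
        )
        assert abs(report["accuracy"].mean() - 0.5) < 0.15

    def test_finetune_improves_code_separability(self):
        x, y = simulate_feature_table(100, 8, structure="nonlinear", seed=0)
        model = train_autoencoder(x, layer_dims=[6, 4, 2], epochs=100, seed=0)
        tuned, head = finetune_with_softmax(model, x, y, epochs=2000, lr=2.0, seed=0, n_restarts=3)
        before = SoftmaxClassifier().fit(fine_features(x, model), y).score(fine_features(x, model), y)
        after = head.score(fine_features(x, tuned), y)
        assert after > before
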