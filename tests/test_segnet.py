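import numpy as np
import pytest

from tumorseg.errors import DegenerateInputError, SizeError, TumorsegError
from tumorseg.phantom import NoiseSpec, PhantomSpec, TumorSpec, generate_dataset
from tumorseg.segnet import (
    FocalLossParams,
    NetworkSpec,
    SegmentationModel,
    TrainingConfig,
    build_fcnn,
    focal_loss,
    focal_loss_grad,
    predict_mask,
    train_segmenter,
)

SMALL = NetworkSpec(n_filters=8)


def _tiny_dataset(n=12, sigma=0.0, seed=0):
    base = PhantomSpec(
        height=32,
        width=32,
        tumor=TumorSpec(radius_px=5.0),
        noise=NoiseSpec(sigma=sigma),
    )
    return generate_dataset(n, 0.5, 3, base, seed=seed)


class TestBuildFcnn:
    def test_output_shape_preserved_with_probabilities_summing_to_one(self, rng):
        model = build_fcnn(NetworkSpec(n_filters=4), seed=0)
        x = rng.normal(size=(2, 1, 24, 24))
        prob = model.predict_proba(x)
        assert prob.shape == (2, 2, 24, 24)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_weights_different_seed_differs(self):
        a = build_fcnn(SMALL, seed=5)
        b = build_fcnn(NetworkSpec(n_filters=8), seed=5)
        c = build_fcnn(NetworkSpec(n_filters=8), seed=6)
        wa = a.net.layers[0].params["W"]
        np.testing.assert_array_equal(wa, b.net.layers[0].params["W"])
        assert not np.array_equal(wa, c.net.layers[0].params["W"])

    def test_first_conv_layer_parameter_count(self):
        model = build_fcnn(NetworkSpec(n_filters=64), seed=0)
        conv = model.net.layers[0]
        assert conv.params["W"].size + conv.params["b"].size == 64 * (3 * 3 * 1) + 64

    def test_indivisible_input_raises_size_error(self):
        model = build_fcnn(SMALL, seed=0)
        with pytest.raises(SizeError):
            predict_mask(model, np.random.default_rng(0).random((30, 30)))

    def test_single_class_rejected(self):
        with pytest.raises(TumorsegError):
            build_fcnn(n_classes=1)


class TestFocalLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        prob = np.zeros((3, 3, 2))
        target = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 1]])
        prob[..., 0] = (target == 0).astype(float)
        prob[..., 1] = (target == 1).astype(float)
        assert focal_loss(prob, target, FocalLossParams(gamma=2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_reduces_to_cross_entropy(self, rng):
        prob = rng.uniform(0.05, 0.95, size=(6, 6, 2))
        prob /= prob.sum(-1, keepdims=True)
        target = rng.integers(0, 2, size=(6, 6))
        weights = np.array([0.7, 1.3])
        got = focal_loss(prob, target, FocalLossParams(gamma=0.0, class_weights=weights))
        # independent cross-entropy implementation
        ce = 0.0
        for i in range(6):
            for j in range(6):
                ce += -weights[target[i, j]] * np.log(prob[i, j, target[i, j]])
        assert got == pytest.approx(ce / 36, abs=1e-9)

    def test_single_pixel_hand_value(self):
        prob = np.array([[[0.1, 0.9]]])
        target = np.array([[1]])
        got = focal_loss(prob, target, FocalLossParams(gamma=2.0))
        assert got == pytest.approx(0.01 * -np.log(0.9), rel=1e-12)

    def test_ignored_pixels_contribute_nothing(self):
        prob = np.full((1, 2, 2), 0.5)
        target = np.array([[1, 255]])
        with_ignore = focal_loss(prob, target, FocalLossParams(gamma=1.0))
        alone = focal_loss(prob[:, :1], target[:, :1], FocalLossParams(gamma=1.0))
        assert with_ignore == pytest.approx(alone)

    def test_all_ignored_raises_degenerate_error(self):
        with pytest.raises(DegenerateInputError):
            focal_loss(np.full((1, 1, 2), 0.5), np.array([[255]]), FocalLossParams())

    def test_loss_nonnegative_and_decreasing_in_true_probability(self):
        params = FocalLossParams(gamma=2.0)
        values = []
        for p in np.linspace(0.05, 0.99, 20):
            prob = np.array([[[1 - p, p]]])
            values.append(focal_loss(prob, np.array([[1]]), params))
        assert all(v >= 0 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("gamma", [0.0, 2.0, 10.0])
    def test_analytic_gradient_matches_numerical(self, gamma, rng):
        prob = rng.uniform(0.1, 0.9, size=(4, 4, 2))
        prob /= prob.sum(-1, keepdims=True)
        target = rng.integers(0, 2, size=(4, 4))
        params = FocalLossParams(gamma=gamma)
        analytic = focal_loss_grad(prob, target, params)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (3, 3, 0)]:
            bumped = prob.copy()
            bumped[idx] += eps
            up = focal_loss(bumped, target, params)
            bumped[idx] -= 2 * eps
            down = focal_loss(bumped, target, params)
            numeric = (up - down) / (2 * eps)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-10)


class TestTrainingConfig:
    def test_published_defaults(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.minibatch_size == 30
        assert cfg.max_epochs == 20
        assert cfg.focal_gamma == 10.0
        assert cfg.shuffle_each_epoch

    def test_invalid_values_rejected(self):
        with pytest.raises(TumorsegError):
            TrainingConfig(learning_rate=0.0)
        with pytest.raises(TumorsegError):
            TrainingConfig(minibatch_size=0)


class TestTrainSegmenter:
    def test_loss_decreases_on_easy_phantoms(self):
        data = _tiny_dataset(n=16, sigma=0.0, seed=4)
        model = build_fcnn(SMALL, seed=1)
        cfg = TrainingConfig(
            max_epochs=4, focal_gamma=2.0, minibatch_size=8, seed=2, validation_fraction=0.0
        )
        _, history = train_segmenter(model, data, cfg)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_identical_seed_reproduces_loss_curve(self):
        cfg = TrainingConfig(
            max_epochs=2, focal_gamma=2.0, minibatch_size=8, seed=3, validation_fraction=0.25
        )
        runs = []
        for _ in range(2):
            data = _tiny_dataset(n=12, sigma=0.05, seed=9)
            model = build_fcnn(NetworkSpec(n_filters=8), seed=7)
            _, history = train_segmenter(model, data, cfg)
            runs.append(history)
        np.testing.assert_array_equal(
            runs[0][["train_loss", "val_loss"]].to_numpy(),
            runs[1][["train_loss", "val_loss"]].to_numpy(),
        )

    def test_empty_dataset_rejected(self):
        from tumorseg.phantom import PhantomDataset

        model = build_fcnn(SMALL, seed=0)
        empty = PhantomDataset([], [], [], [], [])
        with pytest.raises(TumorsegError):
            train_segmenter(model, empty, TrainingConfig())


class TestPredictMask:
    def test_probabilities_normalized_and_labels_binary(self, rng):
        model = build_fcnn(SMALL, seed=0)
        prob, mask = predict_mask(model, rng.random((32, 32)))
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-6)
        assert set(np.unique(mask)) <= {0, 1}
        assert prob.shape == (32, 32, 2)

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path, rng):
        model = build_fcnn(SMALL, seed=3)
        img = rng.random((32, 32))
        prob, _ = predict_mask(model, img)
        path = tmp_path / "seg.npz"
        model.save(str(path))
        reloaded = SegmentationModel.load(str(path))
        prob2, _ = predict_mask(reloaded, img)
        np.testing.assert_allclose(prob, prob2, atol=1e-12)
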