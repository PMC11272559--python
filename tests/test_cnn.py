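"""Network geometry, training dynamics, freezing and feature extraction."""

import numpy as np
import pytest

from p300tl import CNNConfig, TrainConfig, build_cnn, extract_features, fine_tune, train_cnn
from p300tl.cnn import FROZEN_FRONT_END, _LAYER_PARAMS

from conftest import make_epoch_set

TOY = CNNConfig(T=12, C=3, K=2, kernel_height=4, S=4, f=5)


def separable_epochs(n_per_class=40, T=20, C=4, fs=120.0, seed=0):
    """High-amplitude deterministic bump for targets, pure noise for non-targets."""
    rng = np.random.default_rng(seed)
    bump = np.zeros((T, C))
    bump[T // 2 - 2 : T // 2 + 2, :] = 10.0
    pos = bump[None] + 0.1 * rng.standard_normal((n_per_class, T, C))
    neg = 0.1 * rng.standard_normal((n_per_class, T, C))
    epochs = np.concatenate([pos, neg])
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return make_epoch_set(epochs, labels, fs)


class TestGeometry:
    @pytest.mark.parametrize(
        "cfg,positions,flat,f",
        [
            (CNNConfig.for_speller(), 10, 160, 128),  # (160-16)/16 + 1
            (CNNConfig.for_rsvp(), 9, 45, 36),        # (45-5)/5 + 1
        ],
    )
    def test_canonical_configurations(self, cfg, positions, flat, f):
        assert cfg.positions == positions
        assert cfg.flat_dim == flat
        assert cfg.f == f

    def test_feature_layer_wider_than_conv_output_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(T=12, C=3, K=2, kernel_height=4, S=4, f=7)  # flat_dim = 6

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_cnn(TOY, seed=1)
        probs, _ = model.forward(rng.standard_normal((7, 12, 3)), train=False)
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs > 0)

    def test_wrong_input_shape_rejected(self, rng):
        model = build_cnn(TOY, seed=1)
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((7, 13, 3)))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self, rng):
        model = build_cnn(TOY, seed=3)
        x = rng.standard_normal((3, 12, 3))
        y = np.array([0, 1, 1])
        _, grads = model.loss_and_grads(x, y, weight_decay=1e-3, train=True)
        h = 1e-6
        for key in model.trainable_keys():
            arr = model.params[key]
            for _ in range(4):
                idx = tuple(np.unravel_index(rng.integers(arr.size), arr.shape))
                orig = arr[idx]
                arr[idx] = orig + h
                lp, _ = model.loss_and_grads(x, y, 1e-3, train=True)
                arr[idx] = orig - h
                lm, _ = model.loss_and_grads(x, y, 1e-3, train=True)
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(grads[key][idx]), 1e-8)
                assert abs(fd - grads[key][idx]) / denom < 1e-4, key


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self):
        data = separable_epochs(T=12, C=3)
        cfg = TrainConfig(max_epochs=60, patience=60, batch_size=16, seed=0,
                          validation_fraction=0.1)
        model = train_cnn(build_cnn(TOY, seed=0), data, cfg)
        probs, _ = model.forward(data.epochs, train=False)
        acc = ((probs[:, 1] > 0.5).astype(int) == data.labels).mean()
        assert acc >= 0.99

    def test_training_loss_decreases(self):
        data = separable_epochs(T=12, C=3)
        model = train_cnn(build_cnn(TOY, seed=0), data,
                          TrainConfig(max_epochs=20, patience=20, seed=0))
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_zero_learning_rate_is_a_fixed_point(self):
        data = separable_epochs(T=12, C=3)
        init = build_cnn(TOY, seed=2)
        trained = train_cnn(init, data, TrainConfig(learning_rate=0.0, max_epochs=3, seed=0))
        for key in init.trainable_keys():
            assert np.array_equal(trained.params[key], init.params[key])

    def test_weight_decay_shrinks_dense_weights(self):
        data = separable_epochs(T=12, C=3)
        kw = dict(max_epochs=15, patience=15, seed=0)
        with_wd = train_cnn(build_cnn(TOY, seed=1), data, TrainConfig(weight_decay=5e-2, **kw))
        without = train_cnn(build_cnn(TOY, seed=1), data, TrainConfig(weight_decay=0.0, **kw))
        assert np.linalg.norm(with_wd.params["fc1_W"]) < np.linalg.norm(without.params["fc1_W"])

    def test_single_class_data_rejected(self):
        data = separable_epochs(T=12, C=3)
        single = data.subset(np.flatnonzero(data.labels == 1))
        with pytest.raises(ValueError):
            train_cnn(build_cnn(TOY, seed=0), single, TrainConfig(max_epochs=2))

    def test_same_seed_same_parameters(self):
        data = separable_epochs(T=12, C=3)
        cfg = TrainConfig(max_epochs=5, seed=9)
        a = train_cnn(build_cnn(TOY, seed=9), data, cfg)
        b = train_cnn(build_cnn(TOY, seed=9), data, cfg)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])


class TestFineTuning:
    def test_frozen_front_end_is_bit_identical(self):
        source = separable_epochs(T=12, C=3, seed=1)
        target = separable_epochs(T=12, C=3, seed=2)
        pre = train_cnn(build_cnn(TOY, seed=0), source, TrainConfig(max_epochs=8, seed=0))
        tuned = fine_tune(pre, target, TrainConfig(max_epochs=8, seed=1))
        for layer in FROZEN_FRONT_END:
            for key in _LAYER_PARAMS[layer]:
                assert np.array_equal(tuned.params[key], pre.params[key]), key
        assert not np.array_equal(tuned.params["fc1_W"], pre.params["fc1_W"])

    def test_shape_mismatch_rejected(self):
        pre = build_cnn(TOY, seed=0)
        other = separable_epochs(T=16, C=3, seed=1)
        with pytest.raises(ValueError):
            fine_tune(pre, other, TrainConfig(max_epochs=2))


class TestFeatures:
    def test_feature_dimension_and_nonnegativity(self):
        data = separable_epochs(T=12, C=3)
        model = build_cnn(TOY, seed=0)
        feats = extract_features(model, data)
        assert feats.features.shape == (data.n_epochs, TOY.f)
        assert np.all(feats.features >= 0.0)  # post-ReLU
        conv = extract_features(model, data, layer="conv")
        assert conv.features.shape == (data.n_epochs, TOY.flat_dim)

    def test_metadata_carried_over(self):
        data = separable_epochs(T=12, C=3)
        feats = extract_features(build_cnn(TOY, seed=0), data)
        assert np.array_equal(feats.labels, data.labels)

    def test_inference_is_batch_composition_independent(self):
        data = separable_epochs(n_per_class=8, T=12, C=3)
        model = train_cnn(build_cnn(TOY, seed=0), data, TrainConfig(max_epochs=3, seed=0))
        full, _ = model.forward(data.epochs, train=False)
        half1, _ = model.forward(data.epochs[:5], train=False)
        half2, _ = model.forward(data.epochs[5:], train=False)
        assert np.allclose(full, np.vstack([half1, half2]))


def test_checkpoint_roundtrip(tmp_path):
    from p300tl.cnn import CNNModel

    model = build_cnn(TOY, seed=5)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = CNNModel.load(path)
    assert loaded.config == model.config
    for key in model.params:
        assert np.array_equal(loaded.params[key], model.params[key])
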