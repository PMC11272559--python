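"""Discriminative RBM: exact conditional, analytic gradient, training behaviour."""

from itertools import product

import numpy as np
import pytest

from p300tl import DRBMParams, drbm_conditional, predict_proba, train_drbm
from p300tl.drbm import _objective_and_grads, predict_proba_batch

from conftest import make_feature_set


def brute_force_conditional(params: DRBMParams, x: np.ndarray) -> np.ndarray:
    """Explicit sum over all 2^H hidden configurations."""
    h_dim = params.n_hidden
    unnorm = []
    for y in range(params.n_classes):
        total = 0.0
        for h_conf in product([0, 1], repeat=h_dim):
            h = np.array(h_conf, dtype=float)
            total += np.exp(params.b[y] + h @ (params.c + params.U[:, y] + params.W @ x))
        unnorm.append(total)
    unnorm = np.array(unnorm)
    return unnorm / unnorm.sum()


def random_params(rng, h=10, f=4):
    return DRBMParams(
        W=rng.normal(0, 1, (h, f)), c=rng.normal(0, 1, h),
        U=rng.normal(0, 1, (h, 2)), b=rng.normal(0, 1, 2),
    )


class TestConditional:
    def test_zero_parameters_give_uniform_distribution(self):
        params = DRBMParams(W=np.zeros((10, 3)), c=np.zeros(10), U=np.zeros((10, 2)), b=np.zeros(2))
        assert np.allclose(drbm_conditional(params, np.ones(3)), [0.5, 0.5])

    def test_class_bias_closed_form(self):
        params = DRBMParams(W=np.zeros((4, 2)), c=np.zeros(4), U=np.zeros((4, 2)),
                            b=np.array([np.log(3.0), 0.0]))
        assert np.allclose(drbm_conditional(params, np.zeros(2)), [0.75, 0.25])

    @pytest.mark.parametrize("h", [3, 10, 12])
    def test_free_energy_formula_matches_exhaustive_marginalization(self, rng, h):
        params = random_params(rng, h=h, f=4)
        for _ in range(3):
            x = rng.normal(0, 1, 4)
            assert np.allclose(drbm_conditional(params, x), brute_force_conditional(params, x),
                               atol=1e-12)

    def test_nonfinite_input_rejected(self, rng):
        params = random_params(rng)
        with pytest.raises(ValueError):
            drbm_conditional(params, np.array([np.nan, 0, 0, 0]))

    def test_label_symmetry(self, rng):
        params = random_params(rng)
        swapped = DRBMParams(W=params.W, c=params.c, U=params.U[:, ::-1].copy(),
                             b=params.b[::-1].copy())
        x = rng.normal(0, 1, 4)
        assert np.allclose(drbm_conditional(params, x), drbm_conditional(swapped, x)[::-1])


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        params = random_params(rng, h=6, f=3)
        x = rng.normal(0, 1, (5, 3))
        y = np.array([0, 1, 0, 1, 1])
        _, grads = _objective_and_grads(params, x, y)
        h_step = 1e-6
        for name in ("W", "c", "U", "b"):
            arr = getattr(params, name)
            for _ in range(4):
                idx = tuple(np.unravel_index(rng.integers(arr.size), arr.shape))
                orig = arr[idx]
                arr[idx] = orig + h_step
                op, _ = _objective_and_grads(params, x, y)
                arr[idx] = orig - h_step
                om, _ = _objective_and_grads(params, x, y)
                arr[idx] = orig
                fd = (op - om) / (2 * h_step)
                assert abs(fd - grads[name][idx]) / max(abs(fd), 1e-8) < 1e-4

    def test_objective_nondecreasing_under_small_full_batch_steps(self, rng):
        x = rng.normal(0, 1, (30, 3))
        y = (rng.random(30) < 0.5).astype(int)
        params = DRBMParams.init(f=3, n_hidden=5, seed=0)
        prev = -np.inf
        for _ in range(25):
            obj, grads = _objective_and_grads(params, x, y)
            assert obj >= prev - 1e-12
            prev = obj
            for name in ("W", "c", "U", "b"):
                setattr(params, name, getattr(params, name) + 1e-3 * grads[name])


class TestTraining:
    def test_linearly_separable_features_fit_perfectly(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (40, 2)) + [3, 3], rng.normal(0, 0.3, (40, 2))])
        labels = np.array([1] * 40 + [0] * 40)
        feats = make_feature_set(x, labels)
        params = train_drbm(feats, max_epochs=200, seed=0)
        pred = (predict_proba(params, feats) >= 0.5).astype(int)
        assert (pred == labels).mean() == 1.0

    def test_zero_learning_rate_is_fixed_point(self, rng):
        feats = make_feature_set(rng.normal(0, 1, (20, 3)), [0, 1] * 10)
        init = DRBMParams.init(f=3, seed=4)
        trained = train_drbm(feats, learning_rate=0.0, max_epochs=5, seed=4)
        assert np.array_equal(trained.W, init.W)
        assert np.array_equal(trained.b, init.b)

    def test_single_class_rejected(self, rng):
        feats = make_feature_set(rng.normal(0, 1, (10, 3)), [1] * 10)
        with pytest.raises(ValueError):
            train_drbm(feats)

    def test_hybrid_objective_not_implemented(self, rng):
        feats = make_feature_set(rng.normal(0, 1, (10, 3)), [0, 1] * 5)
        with pytest.raises(NotImplementedError):
            train_drbm(feats, alpha=0.5)

    def test_close_to_logistic_regression_on_gaussian_classes(self, rng):
        """On nearly-linear class structure the DRBM should track a linear baseline."""
        from sklearn.linear_model import LogisticRegression

        from p300tl import bca, confusion_counts

        n = 300
        x = np.vstack([rng.normal(1.2, 1.0, (n // 2, 4)), rng.normal(0, 1.0, (n // 2, 4))])
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        x_test = np.vstack([rng.normal(1.2, 1.0, (300, 4)), rng.normal(0, 1.0, (300, 4))])
        y_test = np.array([1] * 300 + [0] * 300)

        params = train_drbm(make_feature_set(x, labels), seed=0)
        drbm_pred = (predict_proba_batch(params, x_test) >= 0.5).astype(int)
        drbm_bca = bca(confusion_counts(y_test, drbm_pred))

        lr = LogisticRegression(max_iter=2000).fit(x, labels)
        lr_bca = bca(confusion_counts(y_test, lr.predict(x_test)))
        assert abs(drbm_bca - lr_bca) <= 0.03 + 1e-9


class TestPrediction:
    def test_identical_inputs_identical_probabilities(self, rng):
        params = random_params(rng)
        x = np.tile(rng.normal(0, 1, 4), (6, 1))
        probs = predict_proba_batch(params, x)
        assert np.allclose(probs, probs[0])
        assert np.all((probs > 0) & (probs < 1))

    def test_probability_complements_class_zero(self, rng):
        params = random_params(rng)
        x = rng.normal(0, 1, 4)
        full = drbm_conditional(params, x)
        assert np.isclose(predict_proba_batch(params, x[None, :])[0], full[1])

    def test_dimension_mismatch_rejected(self, rng):
        params = random_params(rng, f=4)
        with pytest.raises(ValueError):
            predict_proba_batch(params, rng.normal(0, 1, (3, 5)))


def test_params_roundtrip(tmp_path, rng):
    params = random_params(rng)
    path = tmp_path / "drbm.npz"
    params.save(path)
    loaded = DRBMParams.load(path)
    for name in ("W", "c", "U", "b"):
        assert np.array_equal(getattr(loaded, name), getattr(params, name))
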