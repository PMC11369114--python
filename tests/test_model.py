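"""Cost-sensitive losses, training loop, metrics and feature fusion."""

import numpy as np
import pytest

from odorvs.labels import LabelMatrix
from odorvs.model import (
    ClassWeights,
    LossParams,
    ModelConfig,
    combined_loss,
    combined_loss_grad,
    compute_class_weights,
    focal_loss,
    fuse_features,
    micro_metrics,
    train_csmlp,
    wbce_loss,
)
from odorvs.split import SplitResult, iterative_stratified_split


def _random_batch(rng, n=9, c=5):
    y = (rng.random((n, c)) < 0.4).astype(float)
    p = rng.uniform(0.01, 0.99, (n, c))
    w = ClassWeights(rng.uniform(0.1, 0.9, c), rng.uniform(0.1, 0.9, c))
    return y, p, w


class TestClassWeights:
    def test_printed_formula_one_positive_in_ten(self):
        y = np.zeros((10, 1), dtype=int)
        y[0, 0] = 1
        w = compute_class_weights(y)
        assert w.w_pos[0] == pytest.approx(0.9)
        assert w.w_neg[0] == pytest.approx(0.1)

    def test_balanced_class_is_symmetric(self):
        y = np.array([[1], [1], [1], [1], [1], [0], [0], [0], [0], [0]])
        w = compute_class_weights(y)
        assert w.w_pos[0] == w.w_neg[0] == 0.5

    def test_weights_are_complementary(self, rng):
        y = (rng.random((30, 7)) < 0.3).astype(int)
        w = compute_class_weights(y)
        np.testing.assert_allclose(w.w_pos + w.w_neg, 1.0)


class TestLosses:
    def test_focal_zero_when_prediction_perfect(self):
        assert focal_loss(np.array([[1.0]]), np.array([[1.0]]), 2.0, 0.0) == 0.0

    def test_focal_hand_computed_half_probability(self):
        val = focal_loss(np.array([[1.0]]), np.array([[0.5]]), 2.0, 0.0)
        assert val == pytest.approx(0.25 * np.log(2), rel=1e-12)

    def test_focal_gamma_zero_reduces_to_bce(self, rng):
        y, p, _ = _random_batch(rng)
        bce = -np.mean(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p), axis=1))
        assert focal_loss(y, p, 0.0, 0.0) == pytest.approx(bce, abs=1e-10)

    def test_wbce_hand_computed(self):
        w = ClassWeights(np.array([0.9]), np.array([0.1]))
        val = wbce_loss(np.array([[1.0]]), np.array([[0.5]]), w, 1.0, 0.0)
        assert val == pytest.approx(0.9 * np.log(2), rel=1e-12)

    def test_wbce_delta_zero_reduces_to_bce(self, rng):
        y, p, w = _random_batch(rng)
        bce = -np.mean(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p), axis=1))
        assert wbce_loss(y, p, w, 0.0, 0.0) == pytest.approx(bce, abs=1e-10)

    def test_combined_lambda_zero_equals_wbce(self, rng):
        y, p, w = _random_batch(rng)
        params = LossParams(gamma=2.0, delta=0.7, lam=0.0)
        assert combined_loss(y, p, w, params) == pytest.approx(
            wbce_loss(y, p, w, 0.7, params.eps), abs=1e-12)

    def test_combined_monotone_in_lambda(self, rng):
        y, p, w = _random_batch(rng)
        vals = [combined_loss(y, p, w, LossParams(lam=lam))
                for lam in (0.0, 0.5, 1.0, 2.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        y, p, w = _random_batch(rng, n=4, c=3)
        params = LossParams(gamma=2.0, delta=0.5, lam=0.7)
        grad = combined_loss_grad(y, p, w, params)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                pp, pm = p.copy(), p.copy()
                pp[i, j] += eps
                pm[i, j] -= eps
                num = (combined_loss(y, pp, w, params)
                       - combined_loss(y, pm, w, params)) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)

    def test_nan_inputs_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[1.0]]), np.array([[np.nan]]))


class TestMicroMetrics:
    def test_hand_counted_example(self):
        y = np.array([[1, 0], [0, 1]])
        p = np.array([[0.9, 0.8], [0.1, 0.7]])
        prec, rec, f1 = micro_metrics(y, p)
        assert prec == pytest.approx(2 / 3)
        assert rec == pytest.approx(1.0)
        assert f1 == pytest.approx(0.8)

    def test_perfect_prediction(self):
        y = np.array([[1, 0], [0, 1]])
        assert micro_metrics(y, y.astype(float)) == (1.0, 1.0, 1.0)

    def test_all_negative_predictions_with_positives(self):
        y = np.array([[1, 0], [1, 1]])
        p = np.zeros((2, 2))
        prec, rec, f1 = micro_metrics(y, p)
        assert rec == 0.0 and f1 == 0.0


class TestTraining:
    def _separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n, 10))
        x[:, 0] += np.sign(x[:, 0]) * 0.5  # margin along the deciding axis
        y = np.zeros((n, 2), dtype=int)
        y[:, 0] = x[:, 0] > 0
        y[:, 1] = 1 - y[:, 0]
        labels = LabelMatrix([f"m{i}" for i in range(n)], ["a", "b"], y)
        return x, labels

    def test_separable_problem_reaches_high_f1(self):
        x, labels = self._separable()
        split = iterative_stratified_split(labels, 0.25, seed=0)
        net, hist = train_csmlp(
            x, labels, split,
            ModelConfig(epochs=100, seed=0, dropout=0.0, learning_rate=3e-3))
        assert hist.best_f1 >= 0.95

    def test_restored_weights_reproduce_best_f1(self):
        x, labels = self._separable(seed=1)
        split = iterative_stratified_split(labels, 0.25, seed=1)
        net, hist = train_csmlp(
            x, labels, split, ModelConfig(epochs=30, seed=1))
        te = split.test_indices
        _, _, f1 = micro_metrics(labels.matrix[te], net.predict_proba(x[te]))
        assert f1 == pytest.approx(hist.best_f1, abs=1e-12)
        assert hist.best_f1 == max(hist.eval_f1)

    def test_feature_label_mismatch_rejected(self):
        x, labels = self._separable()
        split = iterative_stratified_split(labels, 0.25, seed=0)
        with pytest.raises(ValueError):
            train_csmlp(x[:50], labels, split)

    def test_removed_band_collapses_that_class_recall(self, small_dataset):
        """A class whose spectral evidence is erased becomes unlearnable."""
        cfg, labels, _, gsvs = small_dataset
        grid = np.arange(5, 4001, 5)
        x = gsvs.copy()
        lo, hi = cfg.class_bands[0][0]
        x[:, (grid >= lo - 30) & (grid <= hi + 30)] = 0.0
        split = iterative_stratified_split(labels, 0.25, seed=0)
        net, _ = train_csmlp(x, labels, split,
                             ModelConfig(epochs=60, seed=0))
        te = split.test_indices
        y_hat = net.predict_proba(x[te]) >= 0.5
        y_te = labels.matrix[te]

        def recall(j):
            tp = (y_hat[:, j] & (y_te[:, j] == 1)).sum()
            fn = (~y_hat[:, j] & (y_te[:, j] == 1)).sum()
            return tp / max(tp + fn, 1)

        others = [recall(j) for j in range(1, labels.n_notes)]
        assert recall(0) <= max(others)


class TestFusion:
    def test_component_count_monotone_in_variance_target(self, rng):
        img = rng.normal(0, 1, (60, 40))
        dff = (rng.random((60, 64)) < 0.3).astype(float)
        train = np.arange(45)
        counts = []
        for var in (0.70, 0.75, 0.80, 0.85, 0.90, 0.95):
            _, info = fuse_features(img, dff, train, img_dims=10,
                                    dff_variance=var)
            counts.append(info["dff_components"])
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_output_width_is_sum_of_components(self, rng):
        img = rng.normal(0, 1, (50, 30))
        dff = (rng.random((50, 20)) < 0.4).astype(float)
        fused, info = fuse_features(img, dff, np.arange(40), img_dims=8,
                                    dff_variance=0.8)
        assert fused.shape == (50, info["img_components"] + info["dff_components"])

    def test_fit_uses_train_rows_only(self, rng):
        img = rng.normal(0, 1, (50, 12))
        dff = (rng.random((50, 16)) < 0.4).astype(float)
        train = np.arange(35)
        fused_a, _ = fuse_features(img, dff, train, img_dims=5)
        img_b, dff_b = img.copy(), dff.copy()
        img_b[40:] = rng.normal(0, 1, (10, 12))   # perturb test rows only
        fused_b, _ = fuse_features(img_b, dff_b, train, img_dims=5)
        np.testing.assert_allclose(fused_a[:35], fused_b[:35], atol=1e-10)
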