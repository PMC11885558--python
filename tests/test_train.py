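import numpy as np
import pytest
from scipy.special import log_softmax as sp_log_softmax

from stecg import nn
from stecg.model import build_model, desk_config, ModelConfig
from stecg.train import (TrainConfig, fit, focal_loss, predict,
                         smote_oversample, stratified_split)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self, rng):
        logits = rng.standard_normal((32, 5))
        targets = rng.integers(0, 5, 32)
        ce = -sp_log_softmax(logits, axis=1)[np.arange(32), targets].mean()
        fl = float(focal_loss(logits, targets, gamma=0.0).data)
        assert fl == pytest.approx(ce, abs=1e-7)

    def test_closed_form_single_sample(self):
        # p_y = 0.9, gamma = 2: loss = (1-0.9)^2 * (-ln 0.9)
        p = np.array([0.9, 0.06, 0.04])
        logits = np.log(p)[None, :]
        expected = 0.01 * (-np.log(0.9))
        got = float(focal_loss(logits, np.array([0]), gamma=2.0).data)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_monotone_decreasing_in_confidence(self):
        losses = []
        for p in [0.5, 0.7, 0.9, 0.99, 0.999999]:
            logits = np.log(np.array([[p, 1 - p]]))
            losses.append(float(focal_loss(logits, np.array([0]), 2.0).data))
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-10

    def test_finite_for_extreme_logits(self):
        logits = np.array([[1000.0, -1000.0]])
        assert np.isfinite(float(focal_loss(logits, np.array([1]), 2.0).data))

    def test_alpha_weighting(self, rng):
        logits = rng.standard_normal((16, 3))
        targets = rng.integers(0, 3, 16)
        base = float(focal_loss(logits, targets, 0.0).data)
        double = float(focal_loss(logits, targets, 0.0,
                                  alpha=np.array([2.0, 2.0, 2.0])).data)
        assert double == pytest.approx(2 * base, rel=1e-9)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 3)), np.array([0, 3]))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.repeat([0, 1], 10)
        X2, y2 = smote_oversample(X, y, seed=3)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_counts_equalized_and_convexity(self, rng):
        X = np.vstack([rng.standard_normal((100, 6)),
                       rng.standard_normal((10, 6)) + 5.0])
        y = np.array([0] * 100 + [1] * 10)
        X2, y2 = smote_oversample(X, y, k=5, seed=7)
        assert np.bincount(y2).tolist() == [100, 100]
        # original rows first and untouched
        assert np.array_equal(X2[:110], X)
        minority = X[y == 1]
        for row in X2[110:]:
            assert _lies_on_some_segment(row, minority)

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array([0] * 20 + [1] * 10)
        a = smote_oversample(X, y, seed=5)
        b = smote_oversample(X, y, seed=5)
        c = smote_oversample(X, y, seed=6)
        assert np.array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])

    def test_singleton_class_raises_with_guidance(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="dupl"):
            smote_oversample(X, y)


def _lies_on_some_segment(row, pts, tol=1e-8):
    """Does ``row`` solve x_i + u (x_j - x_i), u in [0,1], for some pair?"""
    for i in range(len(pts)):
        d = pts - pts[i]
        norms = (d ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (d @ (row - pts[i])) / norms
        for j in range(len(pts)):
            if j == i or norms[j] == 0:
                continue
            if -tol <= u[j] <= 1 + tol:
                if np.abs(pts[i] + u[j] * d[j] - row).max() < 1e-6:
                    return True
    return False


def _toy_dataset(rng, n=40, d=(2, 8, 12)):
    """Four linearly separable blobs shaped like tiny TF tensors."""
    X = rng.standard_normal((4 * n,) + d).astype(np.float32) * 0.1
    y = np.repeat(np.arange(4), n)
    for c in range(4):
        X[y == c, c % 2, c % d[1], :] += 3.0
    order = rng.permutation(len(y))
    return X[order], y[order]


@pytest.fixture(scope="module")
def toy_model_and_data():
    rng = np.random.default_rng(42)
    X, y = _toy_dataset(rng)
    cfg = ModelConfig(stage_widths=(4, 8, 8, 8), cardinality=2, embed_dim=8,
                      n_heads=2, ffn_dim=16, head_hidden=8, n_classes=4,
                      input_shape=X.shape[2:])
    return cfg, X, y


class TestFit:
    def test_early_stop_when_val_worsens(self, toy_model_and_data):
        cfg, X, y = toy_model_and_data
        model = build_model(cfg, seed=0)
        # validation labels shuffled so val loss cannot improve for long
        rng = np.random.default_rng(0)
        y_bad = rng.permutation(y[:40])
        tc = TrainConfig(batch_size=16, max_epochs=50, patience=3, seed=0,
                         scheduler="none")
        _, hist = fit(model, (X[40:], y[40:]), (X[:40], y_bad), tc)
        assert "early stop" in hist.stop_reason
        assert len(hist.val_loss) <= hist.best_epoch + 1 + tc.patience

    def test_best_epoch_matches_minimum_val_loss(self, toy_model_and_data):
        cfg, X, y = toy_model_and_data
        model = build_model(cfg, seed=1)
        tc = TrainConfig(batch_size=32, max_epochs=6, patience=5, seed=1)
        _, hist = fit(model, (X[40:], y[40:]), (X[:40], y[:40]), tc)
        assert hist.best_epoch == int(np.argmin(hist.val_loss))

    def test_seed_reproducibility(self, toy_model_and_data):
        cfg, X, y = toy_model_and_data
        tc = TrainConfig(batch_size=32, max_epochs=3, patience=2, seed=9)
        hists = []
        for _ in range(2):
            model = build_model(cfg, seed=5)
            _, h = fit(model, (X[40:], y[40:]), (X[:40], y[:40]), tc)
            hists.append(h)
        np.testing.assert_allclose(hists[0].train_loss, hists[1].train_loss,
                                   atol=1e-6)
        np.testing.assert_allclose(hists[0].val_loss, hists[1].val_loss,
                                   atol=1e-6)

    def test_separable_toy_problem_reaches_high_accuracy(self,
                                                         toy_model_and_data):
        cfg, X, y = toy_model_and_data
        model = build_model(cfg, seed=3)
        # few samples -> few optimizer steps, so the fixture pins a larger
        # step size than the full study uses
        tc = TrainConfig(lr=1e-2, batch_size=32, max_epochs=30, patience=15,
                         seed=3)
        _, hist = fit(model, (X[40:], y[40:]), (X[:40], y[:40]), tc)
        assert max(hist.val_acc) >= 0.9

    def test_empty_split_rejected(self, toy_model_and_data):
        cfg, X, y = toy_model_and_data
        model = build_model(cfg, seed=0)
        with pytest.raises(ValueError):
            fit(model, (X, y), (X[:0], y[:0]), TrainConfig())


class TestPredict:
    def test_argmax_and_tie_rule(self):
        class Stub:
            def eval(self):
                return self

            def __call__(self, t):
                return nn.Tensor(np.array([[0.0, 0.0, 3.0, 0.0],
                                           [1.0, 1.0, 0.0, 0.0]]))

        out = predict(Stub(), np.zeros((2, 1)), batch_size=2)
        assert out.tolist() == [2, 0]

    def test_predict_deterministic(self, toy_model_and_data):
        cfg, X, y = toy_model_and_data
        model = build_model(cfg, seed=4)
        a = predict(model, X[:16])
        b = predict(model, X[:16])
        assert np.array_equal(a, b)


def test_stratified_split_preserves_proportions(rng):
    y = np.repeat([0, 1, 2], [50, 30, 20])
    idx_a, idx_b = stratified_split(y, 0.2, seed=0)
    assert len(idx_a) + len(idx_b) == 100
    assert np.bincount(y[idx_a]).tolist() == [10, 6, 4]
    assert not set(idx_a) & set(idx_b)


def test_train_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(patience=30, max_epochs=20)
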