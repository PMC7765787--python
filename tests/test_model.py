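"""Segment classifier and knowledge head: gradients, contracts, training."""

import numpy as np
import pytest

from kmargin._autodiff import cross_entropy, mse
from kmargin.model import (
    ModelConfig,
    build_model,
    load_checkpoint,
    predict_segment_probs,
    save_checkpoint,
    train,
)

TINY = ModelConfig(
    n_classes=3,
    n_features=2,
    window=600,
    fragment_len=300,
    n_residual_blocks=1,
    conv_channels=4,
    recurrent_units=5,
    knowledge_hidden=6,
    learning_rate=1e-2,
    batch_size=16,
    epochs=5,
    seed=1,
)


def separable_segments(n, rng, window=600):
    """Two waveform families a linear-ish model separates easily: slow vs fast
    oscillation, small additive noise."""
    t = np.arange(window)
    x, y = [], []
    for i in range(n):
        cls = i % 2
        freq = 0.01 if cls == 0 else 0.05
        sig = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        sig = sig + rng.normal(0, 0.1, size=window)
        x.append(sig[None, :])
        y.append(cls)
    return np.array(x), np.array(y)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences agree with the analytic gradients for
        every parameter group of the classifier and knowledge head."""
        clf, head = build_model(TINY, n_channels=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1, 600))
        y = np.array([0, 1, 2])
        zt = rng.normal(size=(6, 2))

        def loss_value():
            frag = clf._fragment_batch(x)
            return float(
                (cross_entropy(clf.forward_logits(x), y) + mse(head.forward(frag), zt)).data
            )

        frag = clf._fragment_batch(x)
        loss = cross_entropy(clf.forward_logits(x), y) + mse(head.forward(frag), zt)
        loss.backward()
        params = {**clf.trunk.params, **clf.params, **head.params}
        for name, p in params.items():
            flat, g = p.data.ravel(), p.grad.ravel()
            for j in (0, flat.size // 2, flat.size - 1):
                eps, old = 1e-6, flat[j]
                flat[j] = old + eps
                up = loss_value()
                flat[j] = old - eps
                down = loss_value()
                flat[j] = old
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(g[j], rel=1e-4, abs=1e-7), name


class TestPredictionContracts:
    def test_valid_simplex_and_determinism(self):
        clf, _ = build_model(TINY, n_channels=1)
        x = np.random.default_rng(2).normal(size=(4, 1, 600))
        p1 = predict_segment_probs(clf, x)
        p2 = predict_segment_probs(clf, x)
        assert p1.shape == (4, 3)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p1 >= 0)
        assert np.array_equal(p1, p2)

    def test_empty_batch(self):
        clf, _ = build_model(TINY, n_channels=1)
        assert predict_segment_probs(clf, np.zeros((0, 1, 600))).shape == (0, 3)

    def test_order_equivariance(self):
        clf, _ = build_model(TINY, n_channels=1)
        x = np.random.default_rng(3).normal(size=(5, 1, 600))
        perm = np.array([3, 0, 4, 1, 2])
        assert np.allclose(
            predict_segment_probs(clf, x)[perm], predict_segment_probs(clf, x[perm])
        )

    def test_wrong_width_rejected(self):
        clf, _ = build_model(TINY, n_channels=1)
        with pytest.raises(ValueError):
            predict_segment_probs(clf, np.zeros((2, 1, 601)))


class TestWeightSharing:
    def test_trunk_objects_are_shared_not_copied(self):
        clf, head = build_model(TINY, n_channels=1)
        for k, v in clf.trunk.params.items():
            assert head.trunk.params[k] is v

    def test_classifier_update_moves_knowledge_output(self):
        """A gradient step through the classifier changes the head's trunk
        activations: the witness that the weights are truly shared."""
        clf, head = build_model(TINY, n_channels=1)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 1, 600))
        frag = clf._fragment_batch(x)
        before = head.predict(frag, standardized=True).copy()
        train(clf, x, np.array([0, 1, 2, 0]), TINY, epochs=1)
        after = head.predict(frag, standardized=True)
        assert not np.allclose(before, after)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(5)
        x, y = separable_segments(50, rng)
        clf, _ = build_model(TINY, n_channels=1)
        trace = train(clf, x, y, TINY, epochs=20)
        assert trace[-1] < trace[0]
        acc = (predict_segment_probs(clf, x).argmax(axis=1) == y).mean()
        assert acc >= 0.95

    def test_reproducible_trace_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        x, y = separable_segments(20, rng)
        clf1, _ = build_model(TINY, n_channels=1)
        clf2, _ = build_model(TINY, n_channels=1)
        t1 = train(clf1, x, y, TINY, epochs=3)
        t2 = train(clf2, x, y, TINY, epochs=3)
        assert t1 == t2  # bit-for-bit

    def test_zero_learning_rate_constant_trace(self):
        import dataclasses

        cfg = dataclasses.replace(TINY, learning_rate=0.0)
        rng = np.random.default_rng(7)
        x, y = separable_segments(16, rng)
        clf, _ = build_model(cfg, n_channels=1)
        trace = train(clf, x, y, cfg, epochs=3)
        assert trace[0] == pytest.approx(trace[1]) and trace[1] == pytest.approx(trace[2])

    def test_empty_training_set_rejected(self):
        clf, _ = build_model(TINY, n_channels=1)
        with pytest.raises(ValueError):
            train(clf, np.zeros((0, 1, 600)), np.zeros(0, dtype=int), TINY)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        clf, head = build_model(TINY, n_channels=1)
        head.set_standardizer(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        head.trained = True
        path = tmp_path / "model.npz"
        save_checkpoint(path, clf, head, extra={"labels": ["a", "b", "c"]})
        clf2, head2, meta = load_checkpoint(path)
        x = np.random.default_rng(8).normal(size=(3, 1, 600))
        assert np.array_equal(
            predict_segment_probs(clf, x), predict_segment_probs(clf2, x)
        )
        frag = clf._fragment_batch(x)
        assert np.array_equal(head.predict(frag), head2.predict(frag))
        assert meta["labels"] == ["a", "b", "c"]
        assert head2.trained
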