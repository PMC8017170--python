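"""The residual CNN + attention-BiLSTM classifier and its layer library."""

import numpy as np
import pytest

from ecgfb.nn.layers import AdditiveAttention, bce_with_logits
from ecgfb.nn.network import (ConstructionError, ModelConfig, ModelHandle,
                              TrainingError, attention_pool, build_model,
                              multilabel_predict, predict, train)

TINY = ModelConfig(frame_count=3, frame_length=60, leads=2,
                   initial_filters=4, initial_kernel=5, initial_stride=1,
                   block1_filters=4, block1_kernel=3, block2_filters=8,
                   block2_kernel=3, block2_stride=2, pool_size=2,
                   lstm_units=4, attention_dim=4, epochs=10,
                   batch_size=8, seed=1)


def tiny_blocks(n, seed=0, separable=False):
    """Random blocks; if separable, class 1 carries a strong DC offset."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3, 60, 2)).astype(np.float32)
    y = (np.arange(n) % 2).astype(int)
    if separable:
        x[y == 1] += 2.0
    return x, y


class TestConstruction:
    def test_forward_returns_probability_per_block(self):
        m = build_model(TINY)
        x, _ = tiny_blocks(4)
        probs = m.predict_proba(x)
        assert probs.shape == (4,)
        assert np.all((probs > 0) & (probs < 1))

    def test_untrained_forward_is_deterministic(self):
        m = build_model(TINY)
        x, _ = tiny_blocks(4)
        np.testing.assert_array_equal(m.predict_proba(x), m.predict_proba(x))

    def test_two_builds_same_seed_identical(self):
        x, _ = tiny_blocks(4)
        a, b = build_model(TINY), build_model(TINY)
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_trunk_layer_census_is_thirteen(self):
        """Conv (6) + batch-norm (6) + max-pool (1) layers of the trunk."""
        census = build_model(TINY).trunk_layer_census()
        assert census == {"conv": 6, "batch_norm": 6, "max_pool": 1,
                          "total": 13}

    def test_shape_mismatch_reports_both_shapes(self):
        m = build_model(TINY)
        with pytest.raises(ConstructionError, match=r"\(3, 60, 2\)"):
            m.forward_logits(np.zeros((2, 3, 50, 2), dtype=np.float32))

    def test_mismatched_block1_filters_rejected(self):
        with pytest.raises(ConstructionError, match="identity"):
            build_model(ModelConfig(block1_filters=16))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            ModelConfig(threshold=1.0)


class TestResidualStructure:
    def test_identity_block_reduces_to_relu_with_zeroed_convs(self):
        """Zero convolution weights: dense block 1 output is ReLU(input)."""
        m = build_model(TINY)
        for conv in (m.block1.conv1, m.block1.conv2):
            conv.w.value[:] = 0.0
            conv.b.value[:] = 0.0
        x = np.random.default_rng(0).normal(size=(3, 30, 4)).astype(np.float32)
        out = m.block1.forward(x, train=True)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-6)

    def test_projection_block_changes_channels_and_stride(self):
        m = build_model(TINY)
        x = np.random.default_rng(0).normal(size=(3, 30, 4)).astype(np.float32)
        out = m.block2.forward(x, train=True)
        assert out.shape == (3, 15, 8)


class TestAttention:
    def test_single_step_gets_weight_one(self):
        seq = np.random.default_rng(0).normal(size=(1, 6))
        context, weights = attention_pool(seq)
        np.testing.assert_allclose(weights, [1.0])
        np.testing.assert_allclose(context, seq[0], atol=1e-6)

    def test_weights_nonnegative_and_normalised(self, rng):
        """1000 random sequences: softmax weights sum to 1 within 1e-6."""
        att = AdditiveAttention(8, 8, np.random.default_rng(3))
        for _ in range(1000):
            seq = rng.normal(size=(int(rng.integers(1, 12)), 8))
            _, w = attention_pool(seq, att)
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-6

    def test_dominant_score_concentrates_context(self):
        """With one step's score far above the rest, the context
        approaches that step (softmax limit)."""
        att = AdditiveAttention(3, 3)
        att.w.value = np.eye(3, dtype=np.float32)
        att.b.value[:] = 0.0
        att.v.value = np.array([50.0, 0.0, 0.0], dtype=np.float32)
        seq = np.array([[-2.0, 1.0, 1.0],
                        [-2.0, 2.0, 2.0],
                        [2.0, 3.0, 3.0]])  # step 2 scores ~+50, others ~-50
        context, weights = attention_pool(seq, att)
        assert weights[2] > 0.999
        np.testing.assert_allclose(context, seq[2], atol=1e-2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            attention_pool(np.zeros((0, 4)))


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        x, y = tiny_blocks(16, separable=True)
        m = train(build_model(TINY), x, y)
        assert m.history["train_loss"][-1] < m.history["train_loss"][0]

    def test_seeded_runs_reproduce_loss_curves(self):
        x, y = tiny_blocks(16, separable=True)
        a = train(build_model(TINY), x, y)
        b = train(build_model(TINY), x, y)
        assert a.history["train_loss"] == b.history["train_loss"]

    def test_single_class_training_rejected(self):
        x, _ = tiny_blocks(8)
        with pytest.raises(TrainingError, match="both classes"):
            train(build_model(TINY), x, np.ones(8))

    def test_separable_task_learned(self):
        x, y = tiny_blocks(32, separable=True)
        m = train(build_model(TINY), x, y)
        probs, calls = predict(m, x)
        assert (calls == y).mean() == 1.0


class TestPredict:
    def test_probability_equal_to_threshold_is_positive(self):
        m = build_model(TINY)
        x, _ = tiny_blocks(4)
        probs, _ = predict(m, x)
        _, calls = predict(m, x, threshold=float(probs[0]))
        assert calls[0] == 1  # boundary inclusive

    def test_near_one_threshold_calls_mostly_zero(self):
        m = build_model(TINY)
        x, _ = tiny_blocks(8)
        _, calls = predict(m, x, threshold=1.0 - 1e-9)
        assert calls.sum() == 0

    def test_calls_monotone_in_threshold(self):
        m = build_model(TINY)
        x, _ = tiny_blocks(12)
        counts = [predict(m, x, threshold=t)[1].sum()
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestMultilabel:
    def _opposite_models(self):
        """Two models pushed to constant positive / negative output."""
        hi, lo = build_model(TINY), build_model(TINY)
        hi.head.b.value[:] = 10.0
        lo.head.b.value[:] = -10.0
        return hi, lo

    def test_union_semantics(self):
        hi, lo = self._opposite_models()
        x, _ = tiny_blocks(3)
        sets = multilabel_predict({"AF": hi, "RBBB": hi, "STD": lo}, x)
        assert all(s == {"AF", "RBBB"} for s in sets)

    def test_all_negative_gives_empty_set(self):
        _, lo = self._opposite_models()
        x, _ = tiny_blocks(2)
        assert multilabel_predict({"AF": lo}, x) == [set(), set()]

    def test_adding_a_model_never_removes_labels(self):
        hi, lo = self._opposite_models()
        x, _ = tiny_blocks(2)
        before = multilabel_predict({"AF": hi}, x)
        after = multilabel_predict({"AF": hi, "PVC": lo}, x)
        for s_before, s_after in zip(before, after):
            assert s_before <= s_after

    def test_missing_model_for_class_rejected(self):
        hi, _ = self._opposite_models()
        x, _ = tiny_blocks(1)
        with pytest.raises(KeyError, match="RBBB"):
            multilabel_predict({"AF": hi}, x, vocabulary=("AF", "RBBB"))


class TestGradients:
    def test_directional_derivative_matches_backprop(self):
        """Finite-difference check of the whole network's gradient along
        random parameter directions."""
        m = build_model(TINY)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3, 60, 2)).astype(np.float32)
        y = (rng.random(8) > 0.5).astype(float)

        for p in m.params():
            p.zero_grad()
        _, dl = bce_with_logits(m.forward_logits(x, train=True), y)
        m._backward(dl, 8)

        ok = 0
        for trial in range(5):
            d = [np.random.default_rng(trial + 10).normal(size=p.value.shape)
                 .astype(np.float32) for p in m.params()]
            gdotd = sum(float((p.grad * di).sum()) for p, di in zip(m.params(), d))
            eps, orig = 1e-3, [p.value.copy() for p in m.params()]
            for p, di in zip(m.params(), d):
                p.value = p.value + eps * di
            lp = bce_with_logits(m.forward_logits(x, train=True), y)[0]
            for p, o, di in zip(m.params(), orig, d):
                p.value = o - eps * di
            lm = bce_with_logits(m.forward_logits(x, train=True), y)[0]
            for p, o in zip(m.params(), orig):
                p.value = o
            num = (lp - lm) / (2 * eps)
            if abs(num - gdotd) / max(abs(num), 1e-9) < 0.05:
                ok += 1
        # occasional max-pool / ReLU boundary flips under perturbation are
        # expected; the majority of directions must agree closely
        assert ok >= 4
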