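"""Stacked auto-encoder: softmax algebra, greedy pretraining, fine-tuning."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstack import (
    SAEModel,
    SoftmaxHead,
    TrainConfig,
    predict_proba,
    pretrain,
    softmax,
    train_ae,
)
from gaitstack.autoencoder import AEParams, encode, init_params
from gaitstack.stacked import (
    build_sae,
    fine_tune,
    fit_head,
    load_model,
    save_model,
    stack_objective_and_grads,
)


class TestSoftmax:
    def test_uniform_on_zero_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), 0.25, atol=1e-15)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, logits, c):
        z = np.array(logits)
        np.testing.assert_allclose(softmax(z + c), softmax(z), atol=1e-12)

    def test_matches_direct_formula(self, rng):
        z = rng.normal(size=6)
        direct = np.array(
            [math.exp(v) / sum(math.exp(u) for u in z) for v in z]
        )
        np.testing.assert_allclose(softmax(z), direct, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        p = softmax(rng.normal(size=(20, 4)) * 30)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestPretrain:
    def test_stack_sizes_chain(self, rng):
        X = rng.uniform(0.1, 0.9, size=(30, 12))
        cfg = TrainConfig(max_epochs=30, seed=1)
        layers = pretrain(X, (10, 15), cfg)
        assert [l.hidden_size for l in layers] == [10, 15]
        assert layers[0].input_size == 12 and layers[1].input_size == 10

    def test_single_layer_equals_plain_autoencoder(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 8))
        cfg = TrainConfig(max_epochs=40, seed=6)
        stack = pretrain(X, (5,), cfg)
        direct, _ = train_ae(X, dataclasses.replace(cfg, hidden_size=5))
        np.testing.assert_array_equal(stack[0].W, direct.W)
        np.testing.assert_array_equal(stack[0].b_dec, direct.b_dec)

    def test_empty_hidden_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            pretrain(rng.uniform(size=(5, 4)), (), TrainConfig())


def _tiny_model(rng, input_size=5, hidden=(4, 3), n_classes=4, zero_head=False):
    layers = []
    prev = input_size
    for i, h in enumerate(hidden):
        layers.append(init_params(prev, h, seed=10 + i))
        prev = h
    names = tuple(f"c{i}" for i in range(n_classes))
    head = (
        SoftmaxHead.zeros(prev, names)
        if zero_head
        else SoftmaxHead(rng.normal(size=(n_classes, prev)), rng.normal(size=n_classes),
                         names)
    )
    return SAEModel(layers=tuple(layers), head=head, config=TrainConfig())


def test_stacked_gradient_check(rng):
    """Central-difference oracle over every encoder block and the head for
    the full softmax cross-entropy objective on a tiny stack."""
    model = _tiny_model(rng)
    X = rng.uniform(0.1, 0.9, size=(6, 5))
    y = rng.integers(0, 4, size=6)
    Y = np.eye(4)[y]
    l2 = 1e-3
    loss, layer_grads, head_grads = stack_objective_and_grads(
        model.layers, model.head, X, Y, l2
    )

    def objective(layers, head):
        l, _, _ = stack_objective_and_grads(layers, head, X, Y, l2)
        return l

    h = 1e-6
    # head blocks
    for attr in ("weights", "biases"):
        base = getattr(model.head, attr)
        num = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sign, store in ((1, "p"), (-1, "m")):
                pert = base.copy()
                pert[idx] += sign * h
                head2 = SoftmaxHead(
                    weights=pert if attr == "weights" else model.head.weights,
                    biases=pert if attr == "biases" else model.head.biases,
                    class_names=model.head.class_names,
                )
                if sign == 1:
                    lp = objective(model.layers, head2)
                else:
                    lm = objective(model.layers, head2)
            num[idx] = (lp - lm) / (2 * h)
        rel = np.abs(head_grads[attr] - num) / np.maximum(np.abs(num), 1e-3)
        assert rel.max() < 1e-6
    # encoder blocks
    for k, layer in enumerate(model.layers):
        for attr in ("W", "b"):
            base = getattr(layer, attr)
            num = np.zeros_like(base)
            it = np.nditer(base, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                vals = []
                for sign in (1, -1):
                    pert = base.copy()
                    pert[idx] += sign * h
                    layers2 = list(model.layers)
                    layers2[k] = dataclasses.replace(layer, **{attr: pert})
                    vals.append(objective(tuple(layers2), model.head))
                num[idx] = (vals[0] - vals[1]) / (2 * h)
            rel = np.abs(layer_grads[k][attr] - num) / np.maximum(np.abs(num), 1e-3)
            assert rel.max() < 1e-6


class TestFineTune:
    def _separable_blobs(self, rng, n=100, d=40):
        half = n // 2
        X = np.vstack(
            [
                rng.uniform(0.0, 0.35, size=(half, d)),
                rng.uniform(0.65, 1.0, size=(n - half, d)),
            ]
        )
        y = np.array(["a"] * half + ["b"] * (n - half), dtype=object)
        return X, y

    def test_reaches_perfect_accuracy_on_separable_classes(self, rng):
        X, y = self._separable_blobs(rng)
        cfg = TrainConfig(max_epochs=3000, learning_rate=0.5, l2_weight=0.0, seed=0)
        model = build_sae(X, y, (6,), cfg)
        pred = np.array(
            [model.head.class_names[i] for i in predict_proba(model, X).argmax(axis=1)]
        )
        assert (pred == y).mean() == 1.0

    def test_zero_learning_rate_keeps_model(self, rng):
        model = _tiny_model(rng)
        X = rng.uniform(0.1, 0.9, size=(8, 5))
        y = np.array(["c0", "c1"] * 4, dtype=object)
        cfg = TrainConfig(max_epochs=20, learning_rate=0.0, tolerance=0.0)
        tuned = fine_tune(model, X, y, cfg)
        np.testing.assert_array_equal(tuned.head.weights, model.head.weights)
        for a, b in zip(tuned.layers, model.layers):
            np.testing.assert_array_equal(a.W, b.W)

    def test_single_class_rejected(self, rng):
        model = _tiny_model(rng)
        X = rng.uniform(size=(4, 5))
        with pytest.raises(ValueError, match="two classes"):
            fine_tune(model, X, np.array(["c0"] * 4), TrainConfig())

    def test_pretraining_not_worse_than_frozen_random_encoders(self, small_split):
        """Pretrained + fine-tuned stacks achieve training cross-entropy no
        higher than a head on frozen random encoders (3 seeds)."""
        train_s, _, _ = small_split
        X, y = train_s.values, train_s.labels
        names = tuple(sorted(set(y.tolist())))
        Y = np.eye(len(names))[[names.index(l) for l in y]]
        for seed in (0, 1, 2):
            cfg = TrainConfig(max_epochs=150, learning_rate=0.5, seed=seed)
            tuned = build_sae(X, y, (12,), cfg, names)
            frozen = SAEModel(
                layers=(init_params(X.shape[1], 12, seed=seed),),
                head=SoftmaxHead.zeros(12, names),
                config=cfg,
            )
            frozen = fit_head(frozen, X, y, cfg)
            ce_tuned, _, _ = stack_objective_and_grads(
                tuned.layers, tuned.head, X, Y, 0.0
            )
            ce_frozen, _, _ = stack_objective_and_grads(
                frozen.layers, frozen.head, X, Y, 0.0
            )
            assert ce_tuned <= ce_frozen + 1e-9


class TestPredictAndPersistence:
    def test_zero_head_gives_uniform_probabilities(self, rng):
        model = _tiny_model(rng, zero_head=True)
        p = predict_proba(model, rng.uniform(size=(5, 5)))
        np.testing.assert_allclose(p, 0.25, atol=1e-15)

    def test_rows_sum_to_one(self, rng):
        model = _tiny_model(rng)
        p = predict_proba(model, rng.uniform(size=(9, 5)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_width_mismatch_rejected(self, rng):
        model = _tiny_model(rng)
        with pytest.raises(ValueError, match="input size mismatch"):
            predict_proba(model, rng.uniform(size=(3, 7)))

    def test_stagewise_composition_oracle(self, rng):
        """predict_proba equals explicit layer-by-layer matrix evaluation."""
        model = _tiny_model(rng)
        X = rng.uniform(size=(7, 5))
        A = X
        for layer in model.layers:
            A = 1 / (1 + np.exp(-(A @ layer.W.T + layer.b)))
        logits = A @ model.head.weights.T + model.head.biases
        expected = np.exp(logits - logits.max(axis=1, keepdims=True))
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(predict_proba(model, X), expected, atol=1e-12)

    def test_serialization_roundtrip_bit_exact(self, rng, tmp_path):
        model = _tiny_model(rng)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for a, b in zip(model.layers, loaded.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.W_dec, b.W_dec)
        np.testing.assert_array_equal(model.head.weights, loaded.head.weights)
        X = rng.uniform(size=(4, 5))
        np.testing.assert_array_equal(
            predict_proba(model, X), predict_proba(loaded, X)
        )

    def test_unrecognized_format_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"format": "something-else", "version": 1}')
        with pytest.raises(ValueError, match="format"):
            load_model(bad)
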