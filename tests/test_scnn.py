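"""Dual-scale sequential CNN: contracts, SE gate, cross-epoch kernels."""

import numpy as np
import pytest

from escnn.scnn import (SCNNClassifier, SCNNConfig, build_scnn, forward,
                        se_recalibrate, train_scnn)
from escnn.seqcodec import encode_sequences

TINY = dict(fs=100.0, n_filters=4, se_reduction=4)


@pytest.fixture(scope="module")
def tiny_model():
    return build_scnn(SCNNConfig(seed=3, **TINY), M=3000)


class TestBuild:
    def test_forward_output_contract(self, tiny_model, rng):
        x = rng.standard_normal((1, 10, 3000)).astype(np.float32)
        p = tiny_model.predict_proba(x)
        assert p.shape == (1, 10, 5)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self):
        m1 = build_scnn(SCNNConfig(seed=9, **TINY), M=3000)
        m2 = build_scnn(SCNNConfig(seed=9, **TINY), M=3000)
        for a, b in zip(m1.net_.params(), m2.net_.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_kernel_wider_than_epoch_rejected(self):
        cfg = SCNNConfig(large_kernel_w=5000, **TINY)
        with pytest.raises(ValueError, match="exceeds"):
            build_scnn(cfg, M=3000)

    def test_se_reduction_must_divide_features(self):
        with pytest.raises(ValueError, match="divisible"):
            SCNNConfig(fs=100.0, n_filters=4, se_reduction=3)


class TestCrossEpochKernels:
    def test_height_two_positions_depend_on_next_epoch(self, rng):
        x = rng.standard_normal((1, 10, 3000)).astype(np.float32)
        x2 = x.copy()
        x2[0, 5] = 0.0                     # zero epoch j+1 = 5
        m2 = build_scnn(SCNNConfig(seed=1, kernel_h=2, **TINY), M=3000)
        m1 = build_scnn(SCNNConfig(seed=1, kernel_h=1, **TINY), M=3000)
        # kernel height 2: position 4 mixes epochs 4 and 5
        d2 = np.abs(m2.predict_proba(x)[0, 4] - m2.predict_proba(x2)[0, 4])
        assert d2.max() > 1e-8
        # kernel height 1 ablation: position 4 sees epoch 4 only
        d1 = np.abs(m1.predict_proba(x)[0, 4] - m1.predict_proba(x2)[0, 4])
        assert d1.max() < 1e-12

    def test_position_independent_of_earlier_epochs(self, rng):
        # with height 2, position j must not see epoch j-1
        x = rng.standard_normal((1, 10, 3000)).astype(np.float32)
        x2 = x.copy()
        x2[0, 3] = 0.0
        m2 = build_scnn(SCNNConfig(seed=1, kernel_h=2, **TINY), M=3000)
        d = np.abs(m2.predict_proba(x)[0, 4] - m2.predict_proba(x2)[0, 4])
        assert d.max() < 1e-12


class TestSE:
    def test_zero_input_zero_output(self):
        w = {"W1": np.zeros((2, 8)), "b1": np.zeros(2),
             "W2": np.zeros((8, 2)), "b2": np.zeros(8)}
        out = se_recalibrate(np.zeros((3, 7, 8)), w)
        np.testing.assert_array_equal(out, 0.0)

    def test_gates_bound_output_below_input(self, rng):
        x = rng.random((4, 6, 8))          # nonnegative features
        w = {"W1": rng.standard_normal((2, 8)), "b1": rng.standard_normal(2),
             "W2": rng.standard_normal((8, 2)), "b2": rng.standard_normal(8)}
        out = se_recalibrate(x, w)
        assert np.all(out <= x + 1e-12)
        assert np.all(out >= 0.0)

    def test_saturated_gate_passes_input_through(self, rng):
        x = rng.random((4, 6, 8))
        w = {"W1": np.zeros((2, 8)), "b1": np.zeros(2),
             "W2": np.zeros((8, 2)), "b2": np.full(8, 20.0)}
        np.testing.assert_allclose(se_recalibrate(x, w), x, atol=1e-6)

    def test_se_block_is_active_in_network(self, tiny_model, rng):
        x = rng.standard_normal((1, 10, 3000)).astype(np.float32)
        base = tiny_model.predict_proba(x)
        saved = []
        for br in (tiny_model.net_.small, tiny_model.net_.large):
            saved.append((br.se.W2.value.copy(), br.se.b2.value.copy()))
            br.se.W2.value[...] = 0.0
            br.se.b2.value[...] = 20.0     # force gates ~ 1
        forced = tiny_model.predict_proba(x)
        for br, (w2, b2) in zip((tiny_model.net_.small,
                                 tiny_model.net_.large), saved):
            br.se.W2.value[...] = w2
            br.se.b2.value[...] = b2
        assert np.abs(base - forced).max() > 1e-8


class TestForward:
    def test_rows_sum_to_one(self, tiny_model, rng):
        seq = encode_sequences(
            rng.standard_normal((15, 3000)).astype(np.float32), L=10)
        probs = forward(tiny_model, seq).probs
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, tiny_model, rng):
        x = rng.standard_normal((3, 10, 3000)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model.predict_proba(x),
                                      tiny_model.predict_proba(x))

    def test_untrained_probabilities_near_uniform(self, rng):
        m = build_scnn(SCNNConfig(seed=17, **TINY), M=3000)
        x = rng.standard_normal((100, 10, 3000)).astype(np.float32)
        p = m.predict_proba(x).reshape(-1, 5)
        assert np.abs(p.mean(axis=0) - 0.2).max() < 0.15

    def test_epoch_length_mismatch_rejected(self, tiny_model, rng):
        seq = encode_sequences(
            rng.standard_normal((12, 1500)).astype(np.float32), L=10)
        with pytest.raises(ValueError, match="does not match"):
            forward(tiny_model, seq)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self, tiny_cohort):
        recs, _ = tiny_cohort
        cfg = SCNNConfig(seed=5, max_epochs=5, min_epochs=1, patience=5,
                         **TINY)
        model = SCNNClassifier(config=cfg)
        train_scnn(model, recs[:2], valid=[recs[2]], L=10)
        return model

    def test_loss_decreases_on_average(self, trained):
        losses = [h["loss"] for h in trained.history_]
        assert losses[-1] < losses[0]

    def test_history_records_every_epoch(self, trained):
        assert {"epoch", "loss", "train_acc", "val_acc"} <= set(
            trained.history_[0])

    def test_training_is_deterministic(self, tiny_cohort):
        recs, _ = tiny_cohort
        cfg = SCNNConfig(seed=6, max_epochs=2, min_epochs=1, patience=2,
                         **TINY)
        hists = []
        for _ in range(2):
            m = SCNNClassifier(config=cfg)
            train_scnn(m, recs[:2], valid=[recs[2]], L=10)
            hists.append(m.history_)
        assert hists[0] == hists[1]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_scnn(SCNNClassifier(config=SCNNConfig(**TINY)), [], L=10)

    def test_mixed_sampling_rates_rejected(self, tiny_cohort):
        recs, _ = tiny_cohort
        import dataclasses
        other = dataclasses.replace(recs[1])
        other.fs = 128.0
        other.labels = recs[1].labels
        with pytest.raises(ValueError, match="sampling rates"):
            train_scnn(SCNNClassifier(config=SCNNConfig(**TINY)),
                       [recs[0], other], L=10)
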