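"""Fusion weights, ensemble prediction and classification metrics."""

import numpy as np
import pytest

from escnn.ensemble import ensemble_predict, fusion_weights
from escnn.metrics import evaluate
from escnn.scnn import SCNNConfig, build_scnn
from escnn.seqcodec import SequenceTensor, decode_consolidate, predict_stages


class TestFusionWeights:
    def test_inverse_square_hand_case(self):
        w = fusion_weights([1.0, 2.0])
        np.testing.assert_allclose(w.weights, [0.8, 0.2], atol=1e-12)

    def test_equal_distances_uniform(self):
        w = fusion_weights([3.0, 3.0, 3.0])
        np.testing.assert_allclose(w.weights, [1 / 3] * 3, atol=1e-12)

    def test_zero_distance_takes_all(self):
        w = fusion_weights([0.0, 5.0])
        np.testing.assert_allclose(w.weights, [1.0, 0.0], atol=1e-12)

    def test_tied_zero_distances_split(self):
        w = fusion_weights([0.0, 0.0, 4.0])
        np.testing.assert_allclose(w.weights, [0.5, 0.5, 0.0], atol=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            fusion_weights([1.0, -0.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_normalized_scale_invariant_monotone(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.random(int(rng.integers(2, 6))) + 0.05
        w = fusion_weights(d)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fusion_weights(d * 37.5).weights,
                                   w.weights, atol=1e-9)
        order = np.argsort(d)
        assert np.all(np.diff(w.weights[order]) <= 1e-12)


class TestEnsemblePredict:
    @pytest.fixture(scope="class")
    def models(self):
        tiny = dict(fs=100.0, n_filters=4, se_reduction=4)
        return [build_scnn(SCNNConfig(seed=s, **tiny), M=3000)
                for s in (1, 2)]

    @pytest.fixture(scope="class")
    def seq(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((14, 3000)).astype(np.float32)
        from escnn.seqcodec import encode_sequences
        return encode_sequences(X, L=10)

    def test_single_model_reduces_to_decode(self, models, seq):
        from escnn.scnn import forward
        w = fusion_weights([1.0])
        pred, cons = ensemble_predict(models[:1], w, seq)
        ref = decode_consolidate(forward(models[0], seq))
        np.testing.assert_allclose(cons.scores, ref.scores, atol=1e-12)
        np.testing.assert_array_equal(pred.stages,
                                      predict_stages(ref).stages)

    def test_identical_models_any_weights(self, models, seq):
        from escnn.scnn import forward
        pair = [models[0], models[0]]
        ref = decode_consolidate(forward(models[0], seq))
        for w in ([0.5, 0.5], [1.0, 3.0]):
            out = ensemble_predict(pair, fusion_weights(w), seq)[1]
            np.testing.assert_allclose(out.scores, ref.scores, atol=1e-9)

    def test_convex_combination_bounds(self, models, seq):
        from escnn.scnn import forward
        w = fusion_weights([1.0, 2.0])
        _, cons = ensemble_predict(models, w, seq)
        s0 = decode_consolidate(forward(models[0], seq)).scores
        s1 = decode_consolidate(forward(models[1], seq)).scores
        lo, hi = np.minimum(s0, s1), np.maximum(s0, s1)
        assert np.all(cons.scores >= lo - 1e-9)
        assert np.all(cons.scores <= hi + 1e-9)

    def test_dominant_weight_wins_disagreement(self):
        class OneHot:
            def __init__(self, stage):
                self.stage = stage

        # hand-built "models": bypass the network by fusing decoded
        # one-hot tensors directly through the weight algebra
        n_win, L = 4, 2
        probs_a = np.zeros((n_win, L, 5))
        probs_a[..., 2] = 1.0                      # model A says N2
        probs_b = np.zeros((n_win, L, 5))
        probs_b[..., 4] = 1.0                      # model B says REM
        w = fusion_weights([1.0, 2.0]).weights     # [0.8, 0.2]
        fused = (w[0] * decode_consolidate(probs_a).scores
                 + w[1] * decode_consolidate(probs_b).scores)
        np.testing.assert_array_equal(predict_stages(fused).stages,
                                      np.full(n_win + L - 1, 2))

    def test_model_weight_count_mismatch(self, models, seq):
        with pytest.raises(ValueError, match="models"):
            ensemble_predict(models, fusion_weights([1.0]), seq)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        rep = evaluate(y, y)
        assert rep.acc == 1.0
        assert rep.kappa == pytest.approx(1.0)
        assert rep.macro_f1 == pytest.approx(1.0)

    def test_binary_confusion_hand_kappa(self):
        # confusion [[50, 10], [10, 30]]: p_o = 0.8, p_e = 0.52
        y_true = np.array([0] * 60 + [1] * 40)
        y_pred = np.array([0] * 50 + [1] * 10 + [0] * 10 + [1] * 30)
        rep = evaluate(y_pred, y_true)
        assert rep.acc == pytest.approx(0.8, abs=1e-12)
        assert rep.kappa == pytest.approx((0.8 - 0.52) / 0.48, abs=1e-10)

    def test_random_predictions_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 5, 10000)
        p = rng.integers(0, 5, 10000)
        assert abs(evaluate(p, y).kappa) < 0.05

    def test_kappa_matches_bruteforce_marginals(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 5, 500)
        p = np.where(rng.random(500) < 0.6, y, rng.integers(0, 5, 500))
        rep = evaluate(p, y)
        cm = rep.confusion.astype(float)
        n = cm.sum()
        po = np.trace(cm) / n
        pe = (cm.sum(1) * cm.sum(0)).sum() / n ** 2
        assert rep.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_confusion_rows_are_true_counts(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 5, 300)
        p = rng.integers(0, 5, 300)
        rep = evaluate(p, y)
        np.testing.assert_array_equal(rep.confusion.sum(1),
                                      np.bincount(y, minlength=5))

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])        # stages N2..REM never occur
        p = np.array([0, 1, 1, 0])
        with pytest.warns(RuntimeWarning, match="absent"):
            rep = evaluate(p, y)
        assert np.isnan(rep.per_class_f1[2:]).all()
        assert np.isfinite(rep.macro_f1)

    def test_auc_from_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.zeros((4, 5))
        scores[np.arange(4), y] = 1.0      # perfectly ranked
        rep = evaluate(y, y, scores)
        assert rep.auc_per_class[0] == pytest.approx(1.0)
        assert rep.auc_per_class[1] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0, 1]), np.array([0, 1, 2]))
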