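"""Confusion-matrix metrics against brute-force oracles; ROC/AUC; CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enhsnap as es
from enhsnap.metrics import ConfusionCounts


def brute_force_metrics(tp, fp, tn, fn):
    """Direct transcription of the defining formulas, kept independent of
    the implementation under test."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return sens, spec, acc, mcc


def rank_statistic_auc(y, scores):
    """P(random positive outscores random negative), ties counted half —
    O(n^2) pairwise oracle."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_four_cell_enumeration(self):
        c = es.confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_and_all_positive(self):
        y = np.array([1, 1, 0, 0, 0])
        perfect = es.confusion(y, y)
        assert perfect.FP == 0 and perfect.FN == 0
        allpos = es.confusion(y, np.ones(5, int))
        assert allpos.TN == 0 and allpos.FP == 3

    def test_length_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            es.confusion([1, 0], [1])
        with pytest.raises(ValueError):
            es.confusion([1, 2], [1, 0])


class TestMetrics:
    def test_agrees_with_brute_force_on_1000_random_tables(self):
        r = np.random.default_rng(99)
        for _ in range(1000):
            tp, fp, tn, fn = r.integers(0, 60, 4)
            if tp + fp + tn + fn == 0:
                tp = 1
            rep = es.metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            sens, spec, acc, mcc = brute_force_metrics(tp, fp, tn, fn)
            assert abs(rep.sensitivity - sens) < 1e-12
            assert abs(rep.specificity - spec) < 1e-12
            assert abs(rep.accuracy - acc) < 1e-12
            assert abs(rep.mcc - mcc) < 1e-12

    def test_published_sensitivity_example(self):
        # 151 of 200 positives recovered -> sensitivity 75.5%
        rep = es.metrics(ConfusionCounts(TP=151, FN=49, TN=152, FP=48))
        assert rep.sensitivity == pytest.approx(0.755)

    def test_perfect_predictor_mcc_one(self):
        rep = es.metrics(ConfusionCounts(TP=100, TN=100, FP=0, FN=0))
        assert rep.mcc == 1.0 and rep.accuracy == 1.0

    def test_balanced_random_table_mcc_zero(self):
        assert es.metrics(ConfusionCounts(1, 1, 1, 1)).mcc == 0.0

    def test_degenerate_marginal_returns_zero_mcc(self):
        assert es.metrics(ConfusionCounts(TP=5, FP=5, TN=0, FN=0)).mcc == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            es.metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_mcc_bounded_and_swap_symmetric(self, cells):
        tp, fp, tn, fn = cells
        if tp + fp + tn + fn == 0:
            return
        mcc = es.metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        assert -1.0 <= mcc <= 1.0
        swapped = es.metrics(ConfusionCounts(tn, fn, tp, fp)).mcc
        assert mcc == pytest.approx(swapped, abs=1e-12)

    def test_matches_sklearn_mcc(self):
        from sklearn.metrics import matthews_corrcoef
        r = np.random.default_rng(3)
        y = r.integers(0, 2, 200)
        pred = r.integers(0, 2, 200)
        ours = es.metrics(es.confusion(y, pred)).mcc
        assert ours == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)


class TestRocAuc:
    def test_perfect_anti_and_endpoints(self):
        y = np.array([0, 0, 1, 1])
        roc, auc = es.roc_auc(y, [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        np.testing.assert_array_equal(roc[0], [0, 0])
        np.testing.assert_array_equal(roc[-1], [1, 1])
        _, anti = es.roc_auc(y, [0.9, 0.8, 0.2, 0.1])
        assert anti == 0.0

    def test_trapezoid_equals_rank_statistic_on_100_vectors(self):
        r = np.random.default_rng(17)
        for i in range(100):
            n = int(r.integers(10, 50))
            y = r.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            # quantized scores force ties into the comparison
            scores = np.round(r.random(n), 2)
            _, auc = es.roc_auc(y, scores)
            assert abs(auc - rank_statistic_auc(y, scores)) < 1e-9

    def test_uninformative_scores_near_half(self):
        r = np.random.default_rng(5)
        y = r.integers(0, 2, 2000)
        _, auc = es.roc_auc(y, r.random(2000))
        assert abs(auc - 0.5) < 0.05       # ~4 sigma of the rank statistic

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            es.roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class _Constant:
    def __init__(self, score):
        self.score = score

    def predict_proba(self, X):
        return np.full(X.shape[0], self.score)


class TestCrossValidate:
    def test_partition_and_determinism(self, tiny_encoded):
        X, y = tiny_encoded
        cfg = es.TrainingConfig(epochs=1, seed=7)
        r1 = es.cross_validate("gru_1x8", X, y.astype(int), k=4, config=cfg,
                               model_factory=lambda s: _Constant(0.6))
        r2 = es.cross_validate("gru_1x8", X, y.astype(int), k=4, config=cfg,
                               model_factory=lambda s: _Constant(0.6))
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        # every sample in exactly one test fold, folds of equal size
        counts = np.bincount(r1.fold_assignments, minlength=4)
        assert (r1.fold_assignments >= 0).all()
        np.testing.assert_array_equal(counts, np.full(4, len(y) // 4))

    def test_constant_classifier_recovers_prevalence(self, tiny_encoded):
        X, y = tiny_encoded
        y = y.astype(int)
        res = es.cross_validate("gru_1x8", X, y, k=4,
                                config=es.TrainingConfig(epochs=1, seed=0),
                                model_factory=lambda s: _Constant(0.9))
        assert res.pooled.accuracy == pytest.approx(y.mean())

    def test_trained_folds_report_pooled_counts(self, tiny_encoded):
        X, y = tiny_encoded
        res = es.cross_validate("gru_1x8", X, y.astype(int), k=2,
                                config=es.TrainingConfig(epochs=2, seed=1))
        assert len(res.fold_reports) == 2
        assert res.pooled.counts.total == len(y)
        assert 0.0 <= res.pooled.auc <= 1.0
        frame = res.to_frame()
        assert list(frame.index) == ["fold0", "fold1", "pooled"]

    def test_k_exceeding_class_count_rejected(self):
        X = np.zeros((6, 4, 10))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            es.cross_validate("gru_1x8", X, y, k=3)
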