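"""Weighted cross-entropy, the cosine-annealing schedule, and the
segmentation metrics, checked against hand-computed values and an
independent library implementation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shredmetric.segnet import (
    ConfusionCounts,
    cosine_annealing_lr,
    evaluate,
    weighted_cross_entropy,
)

W_DEFAULT = np.array([4.0, 4.0, 4.0, 4.0, 1.0])


class TestWeightedCrossEntropy:
    def test_perfect_prediction_gives_zero_loss(self):
        p = np.eye(5)
        labels = np.arange(5)
        assert weighted_cross_entropy(p, labels, W_DEFAULT) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_single_sample(self):
        # true class 0 with weight 4 and p=0.5: loss = 4 ln 2
        p = np.array([[0.5, 0.125, 0.125, 0.125, 0.125]])
        loss = weighted_cross_entropy(p, [0], W_DEFAULT)
        assert loss == pytest.approx(4.0 * math.log(2.0), rel=1e-9)
        assert loss == pytest.approx(2.77259, abs=1e-5)

    def test_unit_weights_reduce_to_plain_cross_entropy(self, rng):
        p = rng.dirichlet(np.ones(5), size=20)
        labels = rng.integers(0, 5, 20)
        ours = weighted_cross_entropy(p, labels, np.ones(5))
        plain = -np.mean(np.log(p[np.arange(20), labels]))
        assert ours == pytest.approx(plain, rel=1e-9)

    @given(scale=st.floats(0.5, 8.0))
    def test_linear_in_weights(self, scale):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(5), size=10)
        labels = rng.integers(0, 5, 10)
        base = weighted_cross_entropy(p, labels, W_DEFAULT)
        scaled = weighted_cross_entropy(p, labels, W_DEFAULT * scale)
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_rows_must_be_distributions(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.array([[0.5, 0.2, 0.1, 0.1, 0.05]]), [0], W_DEFAULT)

    def test_zero_probability_clamped_not_infinite(self, caplog):
        p = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        loss = weighted_cross_entropy(p, [0], W_DEFAULT)
        assert np.isfinite(loss)
        assert loss == pytest.approx(4.0 * -math.log(1e-12), rel=1e-6)


class TestCosineAnnealing:
    def test_period_endpoints_and_midpoint(self):
        eta_min, eta_max, T = 1e-5, 1e-3, 100
        assert cosine_annealing_lr(0, T, eta_min, eta_max) == pytest.approx(eta_max)
        # at the period end the schedule restarts to eta_max; just before
        # it has annealed to (almost) eta_min
        assert cosine_annealing_lr(T, T, eta_min, eta_max) == pytest.approx(eta_max)
        assert cosine_annealing_lr(T - 1, T, eta_min, eta_max) == pytest.approx(
            eta_min, rel=0.05
        )
        assert cosine_annealing_lr(T // 2, T, eta_min, eta_max) == pytest.approx(
            (eta_min + eta_max) / 2
        )

    @given(t=st.integers(0, 1000))
    def test_bounded_for_all_epochs(self, t):
        lr = cosine_annealing_lr(t, 37, 1e-5, 1e-3)
        assert 1e-5 - 1e-15 <= lr <= 1e-3 + 1e-15

    def test_warm_restart_periodicity(self):
        for t in range(50):
            assert cosine_annealing_lr(t, 10, 0.0, 1.0) == pytest.approx(
                cosine_annealing_lr(t + 10, 10, 0.0, 1.0)
            )


class TestMetrics:
    def test_perfect_match_gives_ones(self, rng):
        labels = rng.integers(0, 5, 100)
        rep = evaluate(labels, labels)
        assert rep.miou == rep.mprecision == rep.mrecall == rep.mf1 == 1.0

    def test_hand_computed_counts(self):
        # class 0: TP=8, FP=2, FN=1
        truth = np.array([0] * 9 + [1] * 2 + [1] * 20)
        pred = np.array([0] * 8 + [1] + [0] * 2 + [1] * 20)
        rep = evaluate(pred, truth)
        assert rep.precision[0] == pytest.approx(0.8)
        assert rep.recall[0] == pytest.approx(0.8889, abs=1e-4)
        assert rep.iou[0] == pytest.approx(0.7273, abs=1e-4)
        assert rep.f1[0] == pytest.approx(0.8421, abs=1e-4)

    def test_background_excluded_from_macro_means(self, rng):
        truth = rng.integers(0, 4, 200)
        pred = truth.copy()
        pred[:20] = (truth[:20] + 1) % 4  # some shred-class mistakes
        base = evaluate(pred, truth)
        # append a pile of correctly-classified background points
        truth2 = np.concatenate([truth, np.full(500, 4)])
        pred2 = np.concatenate([pred, np.full(500, 4)])
        with_bg = evaluate(pred2, truth2)
        assert with_bg.miou == pytest.approx(base.miou)
        assert with_bg.mf1 == pytest.approx(base.mf1)

    def test_absent_class_excluded(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 1, 1])
        rep = evaluate(pred, truth)
        assert rep.counted_classes == (0, 1)
        assert rep.miou == 1.0

    def test_matches_sklearn_per_class(self, rng):
        from sklearn.metrics import jaccard_score, precision_score, recall_score

        truth = rng.integers(0, 5, 300)
        pred = rng.integers(0, 5, 300)
        rep = evaluate(pred, truth)
        classes = list(range(5))
        np.testing.assert_allclose(
            rep.precision,
            precision_score(truth, pred, labels=classes, average=None, zero_division=0),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            rep.recall,
            recall_score(truth, pred, labels=classes, average=None, zero_division=0),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            rep.iou,
            jaccard_score(truth, pred, labels=classes, average=None, zero_division=0),
            atol=1e-12,
        )

    def test_confusion_counts_consistency(self, rng):
        truth = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        c = ConfusionCounts.from_labels(pred, truth)
        assert c.tp.sum() + c.fn.sum() == 200  # every point has a true class
        assert c.tp.sum() + c.fp.sum() == 200  # ... and a predicted class
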