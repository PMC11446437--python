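"""Classification metrics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervtriage.metrics import (
    UndefinedMetricError,
    auroc_ovr,
    confusion_matrix,
    evaluate_predictions,
    misclassification_rates,
)


def pairwise_auc_oracle(scores, labels):
    """O(n^2) pair counting: P(pos outranks neg), ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def make_predictions(p_pos, woman_ids=None, positive_class=2):
    n = len(p_pos)
    df = pd.DataFrame(
        {
            "image_id": [f"i{k}" for k in range(n)],
            "woman_id": woman_ids if woman_ids is not None else [f"w{k}" for k in range(n)],
            "p0": np.zeros(n),
            "p1": np.zeros(n),
            "p2": np.zeros(n),
        }
    )
    df[f"p{positive_class}"] = p_pos
    return df


class TestAurocOvr:
    def test_perfect_ranking_gives_one(self):
        truths = np.array([0, 0, 2, 2])
        preds = make_predictions([0.1, 0.2, 0.8, 0.9])
        est = auroc_ovr(preds, truths, positive_class=2, n_boot=10, seed=0)
        assert est.auc == 1.0

    def test_all_tied_scores_give_half(self):
        truths = np.array([0, 0, 2, 2, 2])
        preds = make_predictions(np.full(5, 0.5))
        est = auroc_ovr(preds, truths, positive_class=2, n_boot=10, seed=0)
        assert est.auc == 0.5

    def test_matches_pair_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = np.round(rng.random(30), 2)  # rounding forces ties
            truths = rng.integers(0, 3, size=30)
            if not (0 < (truths == 2).sum() < 30):
                continue
            preds = make_predictions(scores)
            est = auroc_ovr(preds, truths, positive_class=2, n_boot=1, seed=0)
            oracle = pairwise_auc_oracle(scores, (truths == 2).astype(int))
            assert est.auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        truths = rng.integers(0, 3, size=40)
        a = auroc_ovr(make_predictions(scores), truths, 2, n_boot=1, seed=0).auc
        b = auroc_ovr(make_predictions(np.exp(3 * scores)), truths, 2, n_boot=1, seed=0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_test_set_rejected(self):
        truths = np.zeros(5, dtype=int)
        with pytest.raises(UndefinedMetricError):
            auroc_ovr(make_predictions(np.random.rand(5)), truths, 2, n_boot=5)

    def test_ci_brackets_point_and_shrinks_with_sample_size(self):
        def width(n, seed=0):
            rng = np.random.default_rng(seed)
            truths = rng.integers(0, 3, size=n)
            scores = truths / 2 + rng.normal(0, 0.5, size=n)
            est = auroc_ovr(make_predictions(scores), truths, 2, n_boot=200, seed=1)
            assert est.ci_low <= est.auc <= est.ci_high
            return est.ci_high - est.ci_low

        assert width(1000) < width(100)

    def test_bootstrap_resamples_at_woman_level(self):
        """With every image of one woman, resampling can never lose a class
        that the woman herself provides; CI stays defined."""
        truths = np.array([0, 0, 2, 2])
        preds = make_predictions([0.1, 0.2, 0.7, 0.9], woman_ids=["wA"] * 4)
        est = auroc_ovr(preds, truths, 2, n_boot=50, seed=0)
        assert est.n_boot_effective == 50


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        truths = np.array([0, 1, 2, 2])
        preds = pd.DataFrame({"woman_id": "w", "pred_class": [0, 1, 2, 2]})
        c = confusion_matrix(preds, truths)
        assert np.array_equal(c, np.diag([1, 1, 2]))

    def test_no_normal_predictions_pattern(self):
        """A model predicting only indeterminate/precancer+ leaves the
        first prediction column empty."""
        truths = np.array([0, 0, 1, 2])
        preds = pd.DataFrame({"woman_id": "w", "pred_class": [1, 2, 1, 2]})
        c = confusion_matrix(preds, truths)
        assert (c[:, 0] == 0).all()
        assert c.sum() == 4

    def test_matches_loop_oracle(self, rng):
        truths = rng.integers(0, 3, size=200)
        pred_cls = rng.integers(0, 3, size=200)
        preds = pd.DataFrame({"woman_id": "w", "pred_class": pred_cls})
        c = confusion_matrix(preds, truths)
        oracle = np.zeros((3, 3), dtype=int)
        for t, p in zip(truths, pred_cls):
            oracle[t, p] += 1
        assert np.array_equal(c, oracle)


class TestMisclassificationRates:
    def test_perfect_matrix_gives_zero(self):
        assert misclassification_rates(np.diag([5, 3, 2])) == (0.0, 0.0)

    def test_all_mass_in_extreme_corner(self):
        c = np.zeros((3, 3), dtype=int)
        c[0, 2] = 7
        assert misclassification_rates(c) == (100.0, 100.0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            c = rng.integers(0, 30, size=(3, 3))
            if c.sum() == 0:
                continue
            ext, tot = misclassification_rates(c)
            assert ext == pytest.approx(100 * (c[0, 2] + c[2, 0]) / c.sum())
            assert tot == pytest.approx(100 * (c.sum() - c[0, 0] - c[1, 1] - c[2, 2]) / c.sum())

    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
    @settings(max_examples=200, deadline=None)
    def test_extreme_never_exceeds_total(self, cells):
        c = np.array(cells).reshape(3, 3)
        if c.sum() == 0:
            return
        ext, tot = misclassification_rates(c)
        assert 0.0 <= ext <= tot <= 100.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(UndefinedMetricError):
            misclassification_rates(np.zeros((3, 3), dtype=int))


class TestEvaluatePredictions:
    def test_report_fields_are_consistent(self, rng):
        n = 120
        truths = rng.integers(0, 3, size=n)
        probs = rng.dirichlet(np.ones(3), size=n)
        preds = pd.DataFrame(
            {
                "image_id": [f"i{k}" for k in range(n)],
                "woman_id": [f"w{k // 2}" for k in range(n)],
                "p0": probs[:, 0],
                "p1": probs[:, 1],
                "p2": probs[:, 2],
                "score": probs[:, 1] + 2 * probs[:, 2],
                "pred_class": probs.argmax(axis=1),
            }
        )
        rep = evaluate_predictions(preds, truths, n_boot=50, seed=0)
        assert rep.confusion.sum() == n
        assert rep.n_images == n
        assert rep.n_women == 60
        assert 0.0 <= rep.pct_extreme_mis <= rep.pct_total_mis <= 100.0
        assert rep.auroc_normal_vs_rest.ci_low <= rep.auroc_normal_vs_rest.auc
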