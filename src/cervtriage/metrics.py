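"""Classification-performance metrics for the three-class triage problem.

One-vs-rest AUROC with woman-level bootstrap confidence intervals, 3x3
confusion matrices, and the two headline error rates: % extreme
misclassifications (normal called precancer+ or vice versa) and % total
misclassifications.  All metrics are computed at image level (each image
is one unit); the bootstrap resamples women so that correlated repeat
images of the same woman move together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .ground_truth import N_CLASSES

__all__ = [
    "AurocEstimate",
    "MetricsReport",
    "auroc_ovr",
    "confusion_matrix",
    "misclassification_rates",
    "evaluate_predictions",
    "UndefinedMetricError",
]

DEFAULT_N_BOOT = 1000


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. one-class test set)."""


@dataclass(frozen=True)
class AurocEstimate:
    """Point AUROC with a percentile bootstrap confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot_effective: int = 0

    def overlaps(self, other: "AurocEstimate") -> bool:
        """Do the two confidence intervals intersect?"""
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot_effective": self.n_boot_effective,
        }


def auroc_ovr(
    predictions: pd.DataFrame,
    truths: np.ndarray,
    positive_class: int,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> AurocEstimate:
    """One-vs-rest AUROC ranked by the positive class's softmax probability.

    The point estimate is the probability that a positive-class image
    outranks a negative-class one, with ties counted 1/2 (midrank
    correction).  The CI is the 2.5/97.5 percentile interval over
    ``n_boot`` bootstrap resamples drawn at the woman level (all of a
    woman's images enter or leave together); resamples that lose one of
    the two classes are discarded, and ``n_boot_effective`` records how
    many remained.

    Raises :class:`UndefinedMetricError` when the test set has only one
    class after binarisation.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    truths = np.asarray(truths, dtype=int)
    score = predictions[f"p{positive_class}"].to_numpy(float)
    y = (truths == positive_class).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError(
            f"one-vs-rest AUROC for class {positive_class} undefined: one class only"
        )
    point = float(roc_auc_score(y, score))

    rng = np.random.default_rng(seed)
    wids = predictions["woman_id"].to_numpy(object)
    unique_women, inverse = np.unique(wids, return_inverse=True)
    members = [np.flatnonzero(inverse == k) for k in range(len(unique_women))]
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(unique_women), size=len(unique_women))
        idx = np.concatenate([members[k] for k in pick])
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(roc_auc_score(yb, score[idx]))
    if not boots:
        raise UndefinedMetricError("no valid bootstrap resample retained both classes")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AurocEstimate(point, float(lo), float(hi), n_boot_effective=len(boots))


def confusion_matrix(predictions: pd.DataFrame, truths: np.ndarray) -> np.ndarray:
    """3x3 count matrix, rows = truth, columns = predicted class."""
    truths = np.asarray(truths, dtype=int)
    preds = predictions["pred_class"].to_numpy(int)
    return _sk_confusion(truths, preds, labels=list(range(N_CLASSES)))


def misclassification_rates(confusion: np.ndarray) -> tuple[float, float]:
    """(% extreme, % total) misclassification from a 3x3 confusion matrix.

    Extreme misclassifications are the two corner cells: truth normal
    predicted precancer+ and truth precancer+ predicted normal.
    """
    c = np.asarray(confusion)
    if c.shape != (N_CLASSES, N_CLASSES) or np.any(c < 0):
        raise ValueError("confusion must be a nonnegative 3x3 matrix")
    total = c.sum()
    if total == 0:
        raise UndefinedMetricError("misclassification rates undefined for empty matrix")
    pct_extreme = 100.0 * (c[0, 2] + c[2, 0]) / total
    pct_total = 100.0 * (total - np.trace(c)) / total
    return float(pct_extreme), float(pct_total)


@dataclass
class MetricsReport:
    """Classification metrics for one (model, test set) pair."""

    auroc_normal_vs_rest: AurocEstimate
    auroc_precancer_vs_rest: AurocEstimate
    confusion: np.ndarray
    pct_extreme_mis: float
    pct_total_mis: float
    n_images: int
    n_women: int

    def to_json_dict(self) -> dict:
        return {
            "auroc_normal_vs_rest": self.auroc_normal_vs_rest.to_json_dict(),
            "auroc_precancer_vs_rest": self.auroc_precancer_vs_rest.to_json_dict(),
            "confusion": self.confusion.tolist(),
            "pct_extreme_mis": self.pct_extreme_mis,
            "pct_total_mis": self.pct_total_mis,
            "n_images": self.n_images,
            "n_women": self.n_women,
        }


def evaluate_predictions(
    predictions: pd.DataFrame,
    truths: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MetricsReport:
    """Full classification report: both one-vs-rest AUROCs (normal vs rest
    and precancer+ vs rest), confusion matrix and misclassification rates."""
    truths = np.asarray(truths, dtype=int)
    if len(truths) != len(predictions):
        raise ValueError("predictions and truths are not aligned")
    conf = confusion_matrix(predictions, truths)
    pct_ext, pct_tot = misclassification_rates(conf)
    return MetricsReport(
        auroc_normal_vs_rest=auroc_ovr(predictions, truths, 0, n_boot=n_boot, seed=seed),
        auroc_precancer_vs_rest=auroc_ovr(
            predictions, truths, 2, n_boot=n_boot, seed=seed + 1
        ),
        confusion=conf,
        pct_extreme_mis=pct_ext,
        pct_total_mis=pct_tot,
        n_images=int(len(truths)),
        n_women=int(predictions["woman_id"].nunique()),
    )


def roc_curve_points(
    predictions: pd.DataFrame, truths: np.ndarray, positive_class: int
) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold) for CSV export / plotting."""
    from sklearn.metrics import roc_curve

    truths = np.asarray(truths, dtype=int)
    y = (truths == positive_class).astype(int)
    fpr, tpr, thr = roc_curve(y, predictions[f"p{positive_class}"].to_numpy(float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
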