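"""Trainable three-class softmax stand-in classifier.

A multinomial logistic model over image feature vectors stands in for the
convolutional network whose behaviour the evaluation pipeline probes: it
supports out-of-the-box inference, woman-level class-balanced retraining
on combined datasets, and seeded reproducibility, which is all the
pipeline requires of the classifier.

The API follows the model/results idiom: build an
:class:`OrdinalTriageModel` from data, call :meth:`~OrdinalTriageModel.fit`,
and work with the returned :class:`OrdinalTriageResults` (coefficients,
predictions, serialization, ``summary()``).

The continuous severity score of a softmax triple ``p`` is its expected
class index ``sum_i i * p_i``; for three classes it ranges over [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .ground_truth import N_CLASSES

__all__ = [
    "severity_score",
    "softmax",
    "OrdinalTriageModel",
    "OrdinalTriageResults",
    "DegenerateTrainingError",
]


class DegenerateTrainingError(ValueError):
    """Training set does not contain at least two classes."""


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def severity_score(probs: np.ndarray) -> np.ndarray | float:
    """Expected class index of softmax probabilities.

    ``score = sum_i i * p_i`` over classes i = 0..k-1; equivalently the
    expectation of a random variable taking the class labels as values
    with the softmax probabilities.  For three classes the score lies in
    [0, 2]: 0 = confidently normal, 2 = confidently precancer+.
    """
    p = np.asarray(probs, dtype=float)
    idx = np.arange(p.shape[-1], dtype=float)
    out = p @ idx
    return float(out) if np.ndim(out) == 0 else out


def _balanced_woman_subsample(
    woman_ids: np.ndarray,
    woman_classes: dict[str, int],
    ratio: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Woman-level subsample at an N:I:P ratio; returns selected woman ids.

    The scale n is the largest integer with ratio_c * n women available in
    every class with a nonzero ratio entry; sampling is without
    replacement and seeded.
    """
    by_class: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for wid in woman_ids:
        by_class[woman_classes[wid]].append(wid)
    scales = [
        len(by_class[c]) // ratio[c] for c in range(N_CLASSES) if ratio[c] > 0
    ]
    n = min(scales) if scales else 0
    if n == 0:
        raise DegenerateTrainingError(
            f"cannot realise balance ratio {ratio} with per-class woman counts "
            f"{[len(by_class[c]) for c in range(N_CLASSES)]}"
        )
    chosen: list[str] = []
    for c in range(N_CLASSES):
        take = ratio[c] * n
        if take:
            pool = np.array(by_class[c])
            chosen.extend(rng.choice(pool, size=take, replace=False))
    return np.array(chosen)


class OrdinalTriageModel:
    """Multinomial logistic model of ordinal triage class from image features.

    Parameters
    ----------
    features : (n_images, d) array of per-image feature vectors.
    labels : (n_images,) integer classes in {0, 1, 2}.
    woman_ids : per-image woman identifiers; required for woman-level
        class balancing (all of a woman's images move together).
    image_ids : optional per-image identifiers, echoed into predictions.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        woman_ids: Sequence[str] | None = None,
        image_ids: Sequence[str] | None = None,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) aligned with labels")
        if np.any((self.labels < 0) | (self.labels >= N_CLASSES)):
            raise ValueError("labels must lie in {0, 1, 2}")
        self.woman_ids = (
            np.array([f"w{i}" for i in range(len(self.labels))])
            if woman_ids is None
            else np.asarray(woman_ids, dtype=object)
        )
        self.image_ids = (
            np.array([f"img{i}" for i in range(len(self.labels))])
            if image_ids is None
            else np.asarray(image_ids, dtype=object)
        )

    @classmethod
    def from_cohort(cls, cohort: Sequence) -> "OrdinalTriageModel":
        """Build from a list of :class:`~cervtriage.cohort.WomanRecord`."""
        from .cohort import stack_features

        X, y, image_ids, woman_ids = stack_features(cohort)
        return cls(X, y, woman_ids=woman_ids, image_ids=image_ids)

    @classmethod
    def from_frames(cls, women: pd.DataFrame, images: pd.DataFrame) -> "OrdinalTriageModel":
        """Build from women/images tables (format of :mod:`cervtriage.cohort`)."""
        feat_cols = [c for c in images.columns if c.startswith("f")]
        cls_by_woman = dict(zip(women["woman_id"], women["true_class"].astype(int)))
        y = images["woman_id"].map(cls_by_woman).to_numpy(int)
        return cls(
            images[feat_cols].to_numpy(float),
            y,
            woman_ids=images["woman_id"].to_numpy(object),
            image_ids=images["image_id"].to_numpy(object),
        )

    def fit(
        self,
        balance_ratio: tuple[int, int, int] | None = None,
        seed: int = 0,
        max_iter: int = 2000,
        tol: float = 1e-8,
        l2: float = 1e-2,
    ) -> "OrdinalTriageResults":
        """Fit by iterative gradient optimisation to convergence tolerance.

        If ``balance_ratio`` (N, I, P) is given, the training set is first
        subsampled without replacement at the woman level to that ratio.
        Features are standardised with training-set statistics frozen into
        the results.  A small L2 penalty (``l2``) keeps the optimum finite
        on separable data.  Deterministic given ``seed``.
        """
        rng = np.random.default_rng(seed)
        X, y, wids = self.features, self.labels, self.woman_ids
        meta: dict = {"seed": int(seed), "balance_ratio": balance_ratio, "l2": l2}
        if balance_ratio is not None:
            woman_classes: dict[str, int] = {}
            for wid, cls_ in zip(wids, y):
                woman_classes[wid] = int(cls_)
            chosen = set(
                _balanced_woman_subsample(
                    np.array(sorted(woman_classes)), woman_classes, tuple(balance_ratio), rng
                )
            )
            mask = np.array([w in chosen for w in wids])
            X, y = X[mask], y[mask]
            meta["n_women_selected"] = len(chosen)
            meta["selected_woman_ids"] = sorted(chosen)
        present = np.unique(y)
        if len(present) < 2:
            raise DegenerateTrainingError(
                f"training set contains only class(es) {present.tolist()}"
            )
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        clf = LogisticRegression(
            C=1.0 / (l2 * len(y)),
            solver="lbfgs",
            max_iter=max_iter,
            tol=tol,
        )
        clf.fit(Z, y)
        # embed absent classes (if any) with -inf-like logits is not needed:
        # expand coefficient rows to all three classes, missing ones get
        # strongly negative intercepts so they are never predicted
        coef = np.zeros((N_CLASSES, Z.shape[1]))
        intercept = np.full(N_CLASSES, -1e3)
        if len(clf.classes_) == 2:
            # sklearn stores a single contrast row for 2 classes
            c0, c1 = (int(c) for c in clf.classes_)
            coef[c1] = clf.coef_[0]
            intercept[c1] = clf.intercept_[0]
            coef[c0] = 0.0
            intercept[c0] = 0.0
        else:
            for row, c in enumerate(clf.classes_):
                coef[int(c)] = clf.coef_[row]
                intercept[int(c)] = clf.intercept_[row]
        meta.update(
            n_images_fit=int(len(y)),
            n_per_class_fit=[int((y == c).sum()) for c in range(N_CLASSES)],
            n_iter=int(np.max(clf.n_iter_)),
            max_iter=max_iter,
            tol=tol,
        )
        return OrdinalTriageResults(
            coef=coef,
            intercept=intercept,
            feature_mean=mu,
            feature_sd=sd,
            training_meta=meta,
            model=self,
        )


@dataclass
class OrdinalTriageResults:
    """Fitted stand-in classifier: coefficients plus frozen standardisation.

    ``coef`` is (3, d) and ``intercept`` (3,) in standardised feature
    space; ``feature_mean``/``feature_sd`` are the training statistics
    applied to any input before scoring.
    """

    coef: np.ndarray
    intercept: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    training_meta: dict = field(default_factory=dict)
    model: OrdinalTriageModel | None = None

    @property
    def params(self) -> np.ndarray:
        """(3, d+1) weight matrix, intercept in the last column."""
        return np.hstack([self.coef, self.intercept[:, None]])

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.coef.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.coef.shape[1]}"
            )
        Z = (X - self.feature_mean) / self.feature_sd
        return softmax(Z @ self.coef.T + self.intercept)

    def predict(
        self,
        features: np.ndarray,
        image_ids: Sequence[str] | None = None,
        woman_ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Score images: softmax triple, severity score, argmax class.

        Argmax ties break toward the lower (less severe) class.  Returns a
        table with columns image_id, woman_id, p0, p1, p2, score,
        pred_class.
        """
        probs = self.predict_proba(features)
        n = len(probs)
        ids = np.asarray(image_ids, dtype=object) if image_ids is not None else np.array(
            [f"img{i}" for i in range(n)], dtype=object
        )
        wids = np.asarray(woman_ids, dtype=object) if woman_ids is not None else np.array(
            ["" for _ in range(n)], dtype=object
        )
        return pd.DataFrame(
            {
                "image_id": ids,
                "woman_id": wids,
                "p0": probs[:, 0],
                "p1": probs[:, 1],
                "p2": probs[:, 2],
                "score": severity_score(probs),
                "pred_class": np.argmax(probs, axis=1),  # first max = lowest class
            }
        )

    def predict_cohort(self, cohort: Sequence) -> pd.DataFrame:
        from .cohort import stack_features

        X, _, image_ids, woman_ids = stack_features(cohort)
        return self.predict(X, image_ids=image_ids, woman_ids=woman_ids)

    # -- persistence ------------------------------------------------------
    def to_json_dict(self) -> dict:
        meta = {
            k: v for k, v in self.training_meta.items() if k != "selected_woman_ids"
        }
        return {
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "training_meta": meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "OrdinalTriageResults":
        doc = json.loads(Path(path).read_text())
        return cls(
            coef=np.asarray(doc["coef"], float),
            intercept=np.asarray(doc["intercept"], float),
            feature_mean=np.asarray(doc["feature_mean"], float),
            feature_sd=np.asarray(doc["feature_sd"], float),
            training_meta=doc.get("training_meta", {}),
        )

    def summary(self) -> str:
        """Plain-text coefficient table plus training metadata."""
        d = self.coef.shape[1]
        lines = [
            "Ordinal triage stand-in classifier (multinomial logistic)",
            "=" * 60,
            f"features: {d}   classes: normal / indeterminate / precancer+",
        ]
        for k, v in sorted(self.training_meta.items()):
            if k == "selected_woman_ids":
                continue
            lines.append(f"  {k}: {v}")
        lines.append("-" * 60)
        header = "class      intercept " + " ".join(f"{f'f{j + 1}':>8}" for j in range(d))
        lines.append(header)
        names = ("normal", "indeterm.", "precancer")
        for c in range(N_CLASSES):
            row = f"{names[c]:<10} {self.intercept[c]:9.4f} " + " ".join(
                f"{w:8.4f}" for w in self.coef[c]
            )
            lines.append(row)
        return "\n".join(lines)
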