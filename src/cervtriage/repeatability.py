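"""Test-retest repeatability metrics over repeat images per woman.

A repeatable classifier should give near-identical severity scores to
repeat images of the same cervix taken at the same visit.  This module
computes per-woman Bland-Altman statistics — the mean severity score
across a woman's repeat images against the maximum score difference
(max - min) among them — the 95% limits of agreement over those maximum
differences, and the rate of *extreme disagreement*: women for whom some
image pair is predicted normal and precancer+ (two classes apart).

Women contributing a single image carry no repeat information; they are
excluded from all statistics and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlandAltmanPoint",
    "RepeatabilityReport",
    "bland_altman",
    "extreme_disagreement",
    "InsufficientRepeatsError",
]

#: normal-quantile multiplier for 95% limits of agreement
LOA_Z = 1.96


class InsufficientRepeatsError(ValueError):
    """Too few women with repeat images to compute the metric."""


@dataclass(frozen=True)
class BlandAltmanPoint:
    """One woman's (mean score, max score difference) over repeat images."""

    woman_id: str
    mean_score: float
    max_diff: float


@dataclass
class RepeatabilityReport:
    """Bland-Altman repeatability summary for one (model, test set) pair.

    The limits of agreement are centred on the mean per-woman maximum
    difference: ``loa = center +/- 1.96 * sd`` (sample sd, n-1).  Because
    published repeatability numbers do not always say whether "95% LoA"
    means the upper limit, the half-width or the full width, all three are
    exposed: ``loa_high``, ``loa_half_width`` and ``loa_width``.
    """

    points: list[BlandAltmanPoint]
    loa_center: float
    loa_low: float
    loa_high: float
    pct_extreme_disagreement: float
    n_women_evaluable: int
    n_women_single_image: int

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low

    @property
    def loa_half_width(self) -> float:
        return self.loa_width / 2.0

    def points_frame(self) -> pd.DataFrame:
        """Bland-Altman points as a table for CSV export / plotting."""
        return pd.DataFrame(
            [(p.woman_id, p.mean_score, p.max_diff) for p in self.points],
            columns=["woman_id", "mean_score", "max_diff"],
        )

    def to_json_dict(self) -> dict:
        return {
            "loa_center": self.loa_center,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_width": self.loa_width,
            "loa_half_width": self.loa_half_width,
            "pct_extreme_disagreement": self.pct_extreme_disagreement,
            "n_women_evaluable": self.n_women_evaluable,
            "n_women_single_image": self.n_women_single_image,
        }


def _grouped(predictions: pd.DataFrame):
    return predictions.groupby("woman_id", sort=True)


def bland_altman(predictions: pd.DataFrame) -> RepeatabilityReport:
    """Per-woman Bland-Altman analysis of severity-score repeatability.

    ``predictions`` needs columns woman_id, score, pred_class (the format
    written by :meth:`OrdinalTriageResults.predict`).  For each woman with
    >= 2 images the mean score over ALL her repeat images and the maximum
    pairwise score difference (max - min) are computed; the 95% limits of
    agreement are ``mean(max_diff) +/- 1.96 * sd(max_diff)``.

    Raises :class:`InsufficientRepeatsError` with fewer than two evaluable
    women (the sample sd is undefined).
    """
    points: list[BlandAltmanPoint] = []
    n_single = 0
    for wid, g in _grouped(predictions):
        scores = g["score"].to_numpy(float)
        if len(scores) < 2:
            n_single += 1
            continue
        points.append(
            BlandAltmanPoint(
                woman_id=str(wid),
                mean_score=float(scores.mean()),
                max_diff=float(scores.max() - scores.min()),
            )
        )
    if len(points) < 2:
        raise InsufficientRepeatsError(
            f"need >= 2 women with repeat images, found {len(points)}"
        )
    diffs = np.array([p.max_diff for p in points])
    center = float(diffs.mean())
    spread = float(diffs.std(ddof=1))
    return RepeatabilityReport(
        points=points,
        loa_center=center,
        loa_low=center - LOA_Z * spread,
        loa_high=center + LOA_Z * spread,
        pct_extreme_disagreement=extreme_disagreement(predictions),
        n_women_evaluable=len(points),
        n_women_single_image=n_single,
    )


def extreme_disagreement(predictions: pd.DataFrame) -> float:
    """Percent of evaluable women with a normal/precancer+ prediction pair.

    A woman counts as an extreme disagreement when any two of her repeat
    images are predicted two classes apart (class 0 and class 2).  The
    denominator is women with >= 2 images.
    """
    n_evaluable = 0
    n_extreme = 0
    for _, g in _grouped(predictions):
        classes = g["pred_class"].to_numpy(int)
        if len(classes) < 2:
            continue
        n_evaluable += 1
        if (classes == 0).any() and (classes == 2).any():
            n_extreme += 1
    if n_evaluable == 0:
        raise InsufficientRepeatsError("no woman has >= 2 images")
    return 100.0 * n_extreme / n_evaluable
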