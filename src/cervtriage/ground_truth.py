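"""Ground-truth delineation rules and dataset summarization.

Every woman in a screening cohort carries histopathology, high-risk HPV
(hrHPV) and expert-review facts.  These are collapsed into one of three
ordinal ground-truth classes:

    0 = normal, 1 = indeterminate ("gray zone"), 2 = precancer+

The rule engine encodes the standard adjudication hierarchy used in
cervical-screening AI studies: histology CIN3, AIS or invasive cancer is
always precancer+; CIN2 is split by hrHPV status (positive -> precancer+,
negative -> indeterminate); below-CIN2 or missing histology falls through
to the adjudicated expert-review label.  Sites whose referral pathway
guarantees >CIN2 disease (e.g. a LEEP-referral clinic) map every record to
precancer+ and are configured through ``gt_cin2_only_sites`` rather than a
hard-coded site name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NORMAL = 0
INDETERMINATE = 1
PRECANCER = 2

CLASS_NAMES = ("normal", "indeterminate", "precancer+")
N_CLASSES = 3

#: histology readings treated as >=CIN3 (definitive precancer+)
CIN3_PLUS = frozenset({"CIN3", "AIS", "cancer"})
#: histology readings that fall through to the expert-review label
SUB_CIN2 = frozenset({"lt_CIN2", "missing"})

HISTOLOGY_VALUES = frozenset({"lt_CIN2", "missing", "CIN2", "CIN3", "AIS", "cancer"})
HRHPV_VALUES = frozenset({"positive", "negative", "not_tested"})
EXPERT_VALUES = frozenset({"normal", "indeterminate", "absent"})

#: default list of sites whose referral criteria guarantee >CIN2 disease
DEFAULT_GT_CIN2_ONLY_SITES = ("Brazil",)


class UnresolvableRecordError(ValueError):
    """A record whose facts cannot be mapped to a ground-truth class."""


def assign_ground_truth(
    histology: str,
    hrhpv: str,
    expert_label: str,
    site: str,
    gt_cin2_only_sites: Sequence[str] = DEFAULT_GT_CIN2_ONLY_SITES,
) -> int:
    """Map diagnostic facts for one woman to her ordinal class.

    Parameters
    ----------
    histology : one of ``lt_CIN2, missing, CIN2, CIN3, AIS, cancer``.
    hrhpv : one of ``positive, negative, not_tested``.
    expert_label : adjudicated review label, ``normal``/``indeterminate``,
        or ``absent`` when no review was required.
    site : site name; sites in ``gt_cin2_only_sites`` are resolved to
        precancer+ regardless of HPV status.

    Returns
    -------
    int
        0 (normal), 1 (indeterminate) or 2 (precancer+).

    Raises
    ------
    UnresolvableRecordError
        CIN2 without an HPV result outside a >CIN2-only site, or a
        below-CIN2/missing record without an expert label.
    """
    if histology not in HISTOLOGY_VALUES:
        raise ValueError(f"unknown histology value {histology!r}")
    if hrhpv not in HRHPV_VALUES:
        raise ValueError(f"unknown hrHPV value {hrhpv!r}")
    if expert_label not in EXPERT_VALUES:
        raise ValueError(f"unknown expert label {expert_label!r}")

    if histology in CIN3_PLUS:
        return PRECANCER
    if site in gt_cin2_only_sites:
        # referral pathway guarantees >CIN2 disease
        return PRECANCER
    if histology == "CIN2":
        if hrhpv == "positive":
            return PRECANCER
        if hrhpv == "negative":
            return INDETERMINATE
        raise UnresolvableRecordError(
            f"CIN2 record at site {site!r} without an hrHPV result"
        )
    # histology < CIN2 or missing: adjudicated expert label decides
    if expert_label == "normal":
        return NORMAL
    if expert_label == "indeterminate":
        return INDETERMINATE
    raise UnresolvableRecordError(
        f"record with histology {histology!r} at site {site!r} "
        "requires an expert-review label but none is present"
    )


@dataclass
class DatasetSummary:
    """Site x class breakdown of a cohort at image and woman level.

    Both tables are indexed by site with one column per class name plus a
    ``TOTAL`` margin column; a ``TOTAL`` margin row holds column sums.
    """

    image_counts: pd.DataFrame
    woman_counts: pd.DataFrame

    @property
    def n_images(self) -> int:
        return int(self.image_counts.loc["TOTAL", "TOTAL"])

    @property
    def n_women(self) -> int:
        return int(self.woman_counts.loc["TOTAL", "TOTAL"])

    def percentages(self, level: str = "images") -> pd.DataFrame:
        """Cell counts as percent of the grand total (recomputed, never copied)."""
        table = self.image_counts if level == "images" else self.woman_counts
        total = table.loc["TOTAL", "TOTAL"]
        if total == 0:
            return table * np.nan
        return 100.0 * table / total

    def to_json_dict(self) -> dict:
        return {
            "image_counts": {s: self.image_counts.loc[s].to_dict() for s in self.image_counts.index},
            "woman_counts": {s: self.woman_counts.loc[s].to_dict() for s in self.woman_counts.index},
            "n_images": self.n_images,
            "n_women": self.n_women,
        }


def _margined(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["TOTAL"] = table.sum(axis=1)
    table.loc["TOTAL"] = table.sum(axis=0)
    return table.astype(int)


def summarize_dataset(cohort: Iterable) -> DatasetSummary:
    """Tabulate a cohort of :class:`~cervtriage.cohort.WomanRecord` objects.

    Each cell counts images and women at (site, class); margins are sums.
    An empty cohort yields all-zero one-row margin tables.
    """
    rows = [
        {
            "site": w.site,
            "cls": CLASS_NAMES[w.true_class],
            "n_images": len(w.images),
        }
        for w in cohort
    ]
    if not rows:
        empty = pd.DataFrame(0, index=[], columns=list(CLASS_NAMES))
        return DatasetSummary(_margined(empty), _margined(empty))
    df = pd.DataFrame(rows)
    sites = sorted(df["site"].unique())
    shape = pd.DataFrame(0, index=sites, columns=list(CLASS_NAMES))
    images = df.pivot_table(
        index="site", columns="cls", values="n_images", aggfunc="sum", fill_value=0
    )
    women = df.pivot_table(
        index="site", columns="cls", values="n_images", aggfunc="size", fill_value=0
    )
    images = (shape + images.reindex(index=sites, columns=CLASS_NAMES, fill_value=0)).astype(int)
    women = (shape + women.reindex(index=sites, columns=CLASS_NAMES, fill_value=0)).astype(int)
    return DatasetSummary(_margined(images), _margined(women))
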