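"""Experiment suites probing generalizability and repeatability.

Two suites mirror the evaluation design for an ordinal triage classifier
confronted with multi-site, multi-device data:

* :func:`run_heterogeneity_suite` — three runs isolating device- vs
  geography-level dataset shift: (i) train on seed-device data, test on a
  held-aside seed-device set; (ii) the same model applied out of the box
  to the external new-device cohort; (iii) train on seed data plus the
  external cohort minus one held-out geography, test on that geography.

* :func:`run_incremental_retraining` — a ratio-controlled learning curve:
  women from the external cohort are added to the training set in nested
  increments at fixed normal:indeterminate:precancer+ ratios, the model
  is retrained at each increment, and both the external held-aside test
  set and the original seed test set (catastrophic-forgetting check) are
  re-evaluated every time.

Plus :func:`model_panel` (image-level comparison across retrained models
ordered by mean severity score) and :func:`heterogeneity_projection`
(2-D embedding with a silhouette separation statistic per grouping axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    ConfigurationError,
    WomanRecord,
    default_ext_config,
    default_seed_config,
    stack_features,
    subset,
)
from .ground_truth import N_CLASSES
from .metrics import DEFAULT_N_BOOT, MetricsReport, evaluate_predictions
from .model import OrdinalTriageModel, OrdinalTriageResults
from .repeatability import RepeatabilityReport, bland_altman

__all__ = [
    "ExperimentConfig",
    "default_experiment_config",
    "RunResult",
    "RetrainRow",
    "RetrainCurve",
    "run_heterogeneity_suite",
    "run_incremental_retraining",
    "model_panel",
    "heterogeneity_projection",
    "HeterogeneityReport",
    "SamplingError",
]

#: learning-curve increments (number of precancer+ women added per step)
DEFAULT_INCREMENTS = (0, 5, 13, 16, 18, 21, 23, 26, 28, 41, 45, 50, 55, 60, 65, 70)
DEFAULT_RATIOS = ((1, 1, 1), (2, 2, 1))


class SamplingError(ValueError):
    """A requested sample cannot be drawn from the available pool."""


@dataclass
class ExperimentConfig:
    """Everything the two experiment suites need, under one master seed.

    ``heldout_women_per_class`` fixes the class composition of the
    external held-aside test set; when ``None`` it is derived as the
    external class totals minus the maximum training demand over all
    ratios at the largest increment, which both maximises the usable
    training pool and guarantees every increment is feasible.
    """

    seed_cohort_config: CohortConfig
    ext_cohort_config: CohortConfig
    heldout_geography: str = "Bolivia"
    seed_test_fraction: float = 0.3
    heldout_women_per_class: tuple[int, int, int] | None = None
    increments: tuple[int, ...] = DEFAULT_INCREMENTS
    ratios: tuple[tuple[int, int, int], ...] = DEFAULT_RATIOS
    n_boot: int = DEFAULT_N_BOOT
    train_balance_ratio: tuple[int, int, int] | None = (2, 2, 1)
    master_seed: int = 0

    def validate(self) -> None:
        self.seed_cohort_config.validate()
        self.ext_cohort_config.validate()
        if not 0 < self.seed_test_fraction < 1:
            raise ConfigurationError("seed_test_fraction must lie in (0, 1)")
        if list(self.increments) != sorted(set(self.increments)):
            raise ConfigurationError("increments must be strictly increasing")
        ext_geos = {s.site_name for s in self.ext_cohort_config.sites}
        if self.heldout_geography not in ext_geos:
            raise ConfigurationError(
                f"held-out geography {self.heldout_geography!r} not among "
                f"external sites {sorted(ext_geos)}"
            )

    def derived_heldout_counts(self) -> tuple[int, int, int]:
        if self.heldout_women_per_class is not None:
            return tuple(self.heldout_women_per_class)
        totals = np.zeros(N_CLASSES, dtype=int)
        for s in self.ext_cohort_config.sites:
            totals += np.asarray(s.n_women_per_class, dtype=int)
        n_max = max(self.increments)
        demand = np.array(
            [max(r[c] for r in self.ratios) * n_max for c in range(N_CLASSES)]
        )
        held = totals - demand
        if np.any(held < 0):
            raise SamplingError(
                f"external cohort (class totals {totals.tolist()}) cannot supply the "
                f"largest increment demand {demand.tolist()}"
            )
        return tuple(int(h) for h in held)

    def _subseeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.master_seed).generate_state(8)
        names = [
            "seed_split", "heldout_draw", "pool_permutation", "fit",
            "eval_ext", "eval_seed", "panel", "spare",
        ]
        return {name: int(s % (2**31)) for name, s in zip(names, state)}


def default_experiment_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Default study conditions: ~1500-woman seed cohort on two legacy
    devices, 580-woman six-geography external cohort on one new device."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    cfg = ExperimentConfig(
        seed_cohort_config=default_seed_config(seed=int(state[0] % (2**31))),
        ext_cohort_config=default_ext_config(seed=int(state[1] % (2**31))),
        master_seed=master_seed,
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def split_women_stratified(
    cohort: Sequence[WomanRecord], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Class-stratified woman-level train/test split; deterministic."""
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    by_class: dict[int, list[str]] = {c: [] for c in range(N_CLASSES)}
    for w in cohort:
        by_class[w.true_class].append(w.woman_id)
    for c in range(N_CLASSES):
        ids = np.array(by_class[c])
        if len(ids) == 0:
            continue
        n_test = int(round(test_fraction * len(ids)))
        picked = rng.choice(ids, size=n_test, replace=False)
        picked_set = set(picked)
        test_ids.extend(sorted(picked_set))
        train_ids.extend(w for w in ids if w not in picked_set)
    return train_ids, test_ids


def select_heldout(
    ext_cohort: Sequence[WomanRecord],
    counts_per_class: tuple[int, int, int],
    seed: int,
) -> list[str]:
    """Draw the external held-aside test set, stratified by site within class.

    Within each class, the quota is allocated to sites proportionally to
    their class counts (largest-remainder rounding) and sampled without
    replacement; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for c in range(N_CLASSES):
        pools: dict[str, list[str]] = {}
        for w in ext_cohort:
            if w.true_class == c:
                pools.setdefault(w.site, []).append(w.woman_id)
        sites = sorted(pools)
        avail = np.array([len(pools[s]) for s in sites], dtype=int)
        need = counts_per_class[c]
        if need > avail.sum():
            raise SamplingError(
                f"class {c}: requested {need} held-out women, only {avail.sum()} available"
            )
        if need == 0 or avail.sum() == 0:
            continue
        exact = need * avail / avail.sum()
        quota = np.floor(exact).astype(int)
        rem = need - quota.sum()
        order = np.argsort(-(exact - quota))  # largest remainders first
        for j in order[:rem]:
            quota[j] += 1
        quota = np.minimum(quota, avail)
        deficit = need - quota.sum()
        while deficit > 0:  # redistribute if a site hit its ceiling
            for j in np.argsort(-(avail - quota)):
                if quota[j] < avail[j]:
                    quota[j] += 1
                    deficit -= 1
                    break
        for s, q in zip(sites, quota):
            if q:
                chosen.extend(sorted(rng.choice(np.array(pools[s]), size=q, replace=False)))
    return chosen


# ---------------------------------------------------------------------------
# heterogeneity suite (three-run comparison)
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """One train/test run: classification plus repeatability reports."""

    name: str
    metrics: MetricsReport
    repeatability: RepeatabilityReport
    n_train_women: int
    n_test_women: int
    n_test_images: int

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "metrics": self.metrics.to_json_dict(),
            "repeatability": self.repeatability.to_json_dict(),
            "n_train_women": self.n_train_women,
            "n_test_women": self.n_test_women,
            "n_test_images": self.n_test_images,
        }


def _evaluate(
    results: OrdinalTriageResults,
    test_cohort: Sequence[WomanRecord],
    name: str,
    n_train_women: int,
    n_boot: int,
    seed: int,
) -> RunResult:
    X, y, image_ids, woman_ids = stack_features(test_cohort)
    preds = results.predict(X, image_ids=image_ids, woman_ids=woman_ids)
    return RunResult(
        name=name,
        metrics=evaluate_predictions(preds, y, n_boot=n_boot, seed=seed),
        repeatability=bland_altman(preds),
        n_train_women=n_train_women,
        n_test_women=len(test_cohort),
        n_test_images=len(preds),
    )


def run_heterogeneity_suite(
    config: ExperimentConfig,
) -> tuple[dict[str, RunResult], dict]:
    """Three-run device-vs-geography shift comparison.

    Returns ``(runs, manifest)`` with runs keyed ``seed_test`` (i),
    ``ext_oob`` (ii) and ``geo_holdout`` (iii); the manifest records the
    derived sub-seeds and split sizes for reproducibility.
    """
    from .cohort import generate_cohort

    config.validate()
    seeds = config._subseeds()
    seed_cohort = generate_cohort(config.seed_cohort_config)
    ext_cohort = generate_cohort(config.ext_cohort_config)

    train_ids, test_ids = split_women_stratified(
        seed_cohort, config.seed_test_fraction, seeds["seed_split"]
    )
    seed_train = subset(seed_cohort, train_ids)
    seed_test = subset(seed_cohort, test_ids)

    base = OrdinalTriageModel.from_cohort(seed_train).fit(
        balance_ratio=config.train_balance_ratio, seed=seeds["fit"]
    )
    run_i = _evaluate(
        base, seed_test, "seed_test", len(seed_train), config.n_boot, seeds["eval_seed"]
    )
    run_ii = _evaluate(
        base, ext_cohort, "ext_oob", len(seed_train), config.n_boot, seeds["eval_ext"]
    )

    holdout = [w for w in ext_cohort if w.site == config.heldout_geography]
    ext_rest = [w for w in ext_cohort if w.site != config.heldout_geography]
    if not holdout:
        raise ConfigurationError(
            f"no external women at held-out geography {config.heldout_geography!r}"
        )
    combined = seed_train + ext_rest
    geo_model = OrdinalTriageModel.from_cohort(combined).fit(
        balance_ratio=config.train_balance_ratio, seed=seeds["fit"]
    )
    run_iii = _evaluate(
        geo_model, holdout, "geo_holdout", len(combined), config.n_boot, seeds["eval_ext"]
    )

    manifest = {
        "master_seed": config.master_seed,
        "subseeds": seeds,
        "n_seed_train_women": len(seed_train),
        "n_seed_test_women": len(seed_test),
        "n_ext_women": len(ext_cohort),
        "n_holdout_geography_women": len(holdout),
    }
    return {"seed_test": run_i, "ext_oob": run_ii, "geo_holdout": run_iii}, manifest


# ---------------------------------------------------------------------------
# incremental retraining suite
# ---------------------------------------------------------------------------

@dataclass
class RetrainRow:
    """One increment of one ratio arm of the learning curve."""

    ratio: tuple[int, int, int]
    n_added: int  # precancer+ women added (the curve's x-axis)
    women_added_per_class: tuple[int, int, int]
    women_added_total: int
    added_woman_ids: list[str]
    ext_metrics: MetricsReport
    ext_repeatability: RepeatabilityReport
    seed_metrics: MetricsReport


@dataclass
class RetrainCurve:
    """Learning curve for one N:I:P addition ratio."""

    ratio: tuple[int, int, int]
    rows: list[RetrainRow] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "ratio": ":".join(map(str, r.ratio)),
                    "n_added": r.n_added,
                    "women_added_total": r.women_added_total,
                    "ext_auroc_normal": r.ext_metrics.auroc_normal_vs_rest.auc,
                    "ext_auroc_normal_lo": r.ext_metrics.auroc_normal_vs_rest.ci_low,
                    "ext_auroc_normal_hi": r.ext_metrics.auroc_normal_vs_rest.ci_high,
                    "ext_auroc_precancer": r.ext_metrics.auroc_precancer_vs_rest.auc,
                    "ext_auroc_precancer_lo": r.ext_metrics.auroc_precancer_vs_rest.ci_low,
                    "ext_auroc_precancer_hi": r.ext_metrics.auroc_precancer_vs_rest.ci_high,
                    "ext_pct_extreme_mis": r.ext_metrics.pct_extreme_mis,
                    "ext_pct_total_mis": r.ext_metrics.pct_total_mis,
                    "ext_pct_extreme_dis": r.ext_repeatability.pct_extreme_disagreement,
                    "ext_loa_width": r.ext_repeatability.loa_width,
                    "ext_loa_half_width": r.ext_repeatability.loa_half_width,
                    "seed_auroc_normal": r.seed_metrics.auroc_normal_vs_rest.auc,
                    "seed_auroc_precancer": r.seed_metrics.auroc_precancer_vs_rest.auc,
                    "seed_pct_extreme_mis": r.seed_metrics.pct_extreme_mis,
                    "seed_pct_total_mis": r.seed_metrics.pct_total_mis,
                }
            )
        return pd.DataFrame(recs)

    def plateau_n(self, metric: str = "ext_auroc_precancer", tol: float = 0.01) -> int:
        """Smallest increment whose AUROC is within ``tol`` of the curve max."""
        frame = self.as_frame()
        best = frame[metric].max()
        ok = frame[frame[metric] >= best - tol]
        return int(ok["n_added"].iloc[0])


def run_incremental_retraining(
    config: ExperimentConfig,
) -> tuple[dict[tuple[int, int, int], RetrainCurve], dict]:
    """Ratio-controlled incremental retraining with a fixed held-aside set.

    For each ratio (N, I, P) and each increment n, the first ``ratio_c*n``
    women of each class are taken from a seeded per-class permutation of
    the external training pool (so selections are nested across
    increments), stacked onto the frozen class-balanced seed training
    subsample, and the model is refit.  Every increment is evaluated on
    the same external held-aside test set and re-evaluated on the seed
    test set to monitor catastrophic forgetting.  ``n = 0`` is the
    out-of-the-box baseline.

    Returns ``(curves, manifest)`` with one :class:`RetrainCurve` per ratio.
    """
    from .cohort import generate_cohort

    config.validate()
    seeds = config._subseeds()
    seed_cohort = generate_cohort(config.seed_cohort_config)
    ext_cohort = generate_cohort(config.ext_cohort_config)

    train_ids, test_ids = split_women_stratified(
        seed_cohort, config.seed_test_fraction, seeds["seed_split"]
    )
    seed_train = subset(seed_cohort, train_ids)
    seed_test = subset(seed_cohort, test_ids)

    heldout_counts = config.derived_heldout_counts()
    heldout_ids = select_heldout(ext_cohort, heldout_counts, seeds["heldout_draw"])
    heldout_set = set(heldout_ids)
    heldout = subset(ext_cohort, heldout_ids)
    pool = [w for w in ext_cohort if w.woman_id not in heldout_set]

    # frozen class-balanced seed training subsample = the baseline model's
    # training set; increments stack external women on top of it
    base = OrdinalTriageModel.from_cohort(seed_train).fit(
        balance_ratio=config.train_balance_ratio, seed=seeds["fit"]
    )
    if config.train_balance_ratio is not None:
        frozen_ids = base.training_meta["selected_woman_ids"]
        seed_portion = subset(seed_train, frozen_ids)
    else:
        seed_portion = seed_train

    rng = np.random.default_rng(seeds["pool_permutation"])
    perms: dict[int, list[str]] = {}
    for c in range(N_CLASSES):
        ids = np.array(sorted(w.woman_id for w in pool if w.true_class == c))
        perms[c] = list(rng.permutation(ids)) if len(ids) else []

    seed_X, seed_y, seed_img, seed_wid = stack_features(seed_test)
    ext_X, ext_y, ext_img, ext_wid = stack_features(heldout)

    curves: dict[tuple[int, int, int], RetrainCurve] = {}
    for ratio in config.ratios:
        curve = RetrainCurve(ratio=tuple(ratio))
        for n in config.increments:
            per_class = tuple(ratio[c] * n for c in range(N_CLASSES))
            for c in range(N_CLASSES):
                if per_class[c] > len(perms[c]):
                    raise SamplingError(
                        f"ratio {ratio} increment {n}: needs {per_class[c]} class-{c} "
                        f"women, pool has {len(perms[c])}"
                    )
            added_ids = [
                wid for c in range(N_CLASSES) for wid in perms[c][: per_class[c]]
            ]
            if n == 0:
                results = base
            else:
                added = subset(ext_cohort, added_ids)
                results = OrdinalTriageModel.from_cohort(seed_portion + added).fit(
                    balance_ratio=None, seed=seeds["fit"]
                )
            ext_preds = results.predict(ext_X, image_ids=ext_img, woman_ids=ext_wid)
            seed_preds = results.predict(seed_X, image_ids=seed_img, woman_ids=seed_wid)
            curve.rows.append(
                RetrainRow(
                    ratio=tuple(ratio),
                    n_added=n,
                    women_added_per_class=per_class,
                    women_added_total=sum(per_class),
                    added_woman_ids=added_ids,
                    ext_metrics=evaluate_predictions(
                        ext_preds, ext_y, n_boot=config.n_boot, seed=seeds["eval_ext"]
                    ),
                    ext_repeatability=bland_altman(ext_preds),
                    seed_metrics=evaluate_predictions(
                        seed_preds, seed_y, n_boot=config.n_boot, seed=seeds["eval_seed"]
                    ),
                )
            )
        curves[tuple(ratio)] = curve

    manifest = {
        "master_seed": config.master_seed,
        "subseeds": seeds,
        "heldout_women_per_class": list(heldout_counts),
        "n_heldout_women": len(heldout),
        "n_heldout_images": int(len(ext_y)),
        "heldout_woman_ids": sorted(heldout_ids),
        "n_pool_women_per_class": [len(perms[c]) for c in range(N_CLASSES)],
        "n_seed_portion_women": len(seed_portion),
    }
    return curves, manifest


# ---------------------------------------------------------------------------
# model panel (image-level comparison across models)
# ---------------------------------------------------------------------------

def model_panel(
    models: Sequence[OrdinalTriageResults],
    features: np.ndarray,
    truths: np.ndarray,
    image_ids: Sequence[str],
    per_class: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-model comparison panel over severity-score-ordered images.

    Each image's severity score is averaged over all models; within each
    truth class images are sorted by ascending mean score, and
    ``per_class`` images are drawn by quantile-stratified random selection
    (one per contiguous score bin) so the selection preserves the mean
    score distribution.  Columns: image_id, true_class, mean_score, and
    the predicted class under every model.
    """
    if len(models) == 0:
        raise ValueError("need at least one model")
    features = np.asarray(features, dtype=float)
    truths = np.asarray(truths, dtype=int)
    rng = np.random.default_rng(seed)

    scores = np.stack([m.predict(features)["score"].to_numpy() for m in models])
    mean_score = scores.mean(axis=0)
    pred_classes = np.stack(
        [m.predict(features)["pred_class"].to_numpy() for m in models]
    )

    blocks = []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(truths == c)
        if len(idx) == 0:
            continue
        if per_class > len(idx):
            raise ValueError(
                f"per_class={per_class} exceeds the {len(idx)} images of class {c}"
            )
        order = idx[np.argsort(mean_score[idx], kind="stable")]
        if per_class == len(order):
            sel = order
        else:
            bins = np.array_split(order, per_class)
            sel = np.array([b[rng.integers(0, len(b))] for b in bins])
        for i in sel:
            blocks.append(
                {
                    "image_id": image_ids[i],
                    "true_class": int(truths[i]),
                    "mean_score": float(mean_score[i]),
                }
                | {f"model_{m}": int(pred_classes[m, i]) for m in range(len(models))}
            )
    return pd.DataFrame(blocks)


# ---------------------------------------------------------------------------
# heterogeneity projection (embedding + separation statistic)
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityReport:
    """2-D embedding plus per-axis silhouette separation scores."""

    embedding: np.ndarray
    separation: dict[str, float]

    def to_json_dict(self) -> dict:
        return {"separation": self.separation, "n_points": int(len(self.embedding))}


def group_separation(points: np.ndarray, labels: Sequence) -> float:
    """Silhouette separation of labelled groups (-1 mixed .. 1 separated)."""
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("separation undefined for a single group")
    return float(silhouette_score(points, labels))


def heterogeneity_projection(
    features: np.ndarray,
    axes: dict[str, Sequence],
    method: str = "pca",
    seed: int = 0,
) -> HeterogeneityReport:
    """Project features to 2-D and score group separation per axis.

    ``axes`` maps axis names (e.g. ``device``, ``geography``) to per-image
    labels.  ``method`` is ``"pca"`` (variance-preserving linear
    projection, dependency-free default) or ``"umap"`` when umap-learn is
    installed.  The separation statistic is the silhouette score of each
    labelling evaluated on the 2-D embedding.
    """
    features = np.asarray(features, dtype=float)
    if method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=seed).fit_transform(features)
    elif method == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(features)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    separation = {name: group_separation(emb, labels) for name, labels in axes.items()}
    return HeterogeneityReport(embedding=emb, separation=separation)
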