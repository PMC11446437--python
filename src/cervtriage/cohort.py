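"""Synthetic multi-site, multi-device screening cohort generator.

The generator emulates the statistical structure that the downstream
evaluation pipeline assumes, without any real images:

* per-image feature vectors stand in for CNN embeddings;
* the three ordinal classes are class-conditional Gaussians with equally
  spaced means along a single *severity axis* (feature 0);
* each capture device adds a large translation in a subspace orthogonal to
  the severity axis, and may *rotate* the severity axis (``severity_axis``):
  a camera never seen in training relocates the embedding cluster and also
  encodes the same pathology signal along a partially different feature
  direction, so a model trained on the old devices projects onto the wrong
  axis until it is retrained;
* each geography/site adds a small translation, so device-level shift
  dominates geography-level shift;
* every woman contributes 1-4 repeat images that share a woman-level
  random effect, producing the within-woman correlation that
  Bland-Altman repeatability analysis relies on.

Diagnostic facts (histology, hrHPV, expert review label) are generated to
be exactly consistent with the woman's true class under the rule engine in
:mod:`cervtriage.ground_truth`, so assigning ground truth to a generated
cohort recovers the simulated classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd
import yaml

from .ground_truth import (
    CLASS_NAMES,
    DEFAULT_GT_CIN2_ONLY_SITES,
    INDETERMINATE,
    NORMAL,
    PRECANCER,
)


class ConfigurationError(ValueError):
    """Invalid cohort or experiment configuration."""


@dataclass(frozen=True)
class SiteSpec:
    """One collection site: a geography bound to a capture device.

    ``geo_shift`` and ``device_shift`` are translations added to every
    class mean at the site; under the default configuration the device
    shift dominates the geography shift.  ``severity_axis``, when given,
    replaces the global severity direction (feature 0) for this site's
    device: its direction is the axis along which class means are spaced
    and its norm scales the separation (a unit vector keeps the signal
    strength, merely rotating it).  ``gt_cin2_only`` marks sites whose
    referral pathway guarantees >CIN2 disease, so every record resolves to
    precancer+.
    """

    site_name: str
    device: str
    n_women_per_class: tuple[int, int, int]
    geo_shift: np.ndarray
    device_shift: np.ndarray
    severity_axis: np.ndarray | None = None
    gt_cin2_only: bool = False

    def validate(self, n_features: int) -> None:
        if len(self.n_women_per_class) != 3 or any(n < 0 for n in self.n_women_per_class):
            raise ConfigurationError(
                f"site {self.site_name!r}: n_women_per_class must be 3 nonnegative ints"
            )
        for name, vec in (("geo_shift", self.geo_shift), ("device_shift", self.device_shift)):
            if np.asarray(vec).shape != (n_features,):
                raise ConfigurationError(
                    f"site {self.site_name!r}: {name} must have length {n_features}"
                )
        if self.severity_axis is not None:
            axis = np.asarray(self.severity_axis)
            if axis.shape != (n_features,):
                raise ConfigurationError(
                    f"site {self.site_name!r}: severity_axis must have length {n_features}"
                )
            if np.linalg.norm(axis) == 0:
                raise ConfigurationError(
                    f"site {self.site_name!r}: severity_axis must be nonzero"
                )
        if self.gt_cin2_only and (
            self.n_women_per_class[NORMAL] > 0 or self.n_women_per_class[INDETERMINATE] > 0
        ):
            raise ConfigurationError(
                f"site {self.site_name!r} is >CIN2-only but requests non-precancer+ women"
            )


DEFAULT_IMAGES_PER_WOMAN = {1: 0.10, 2: 0.45, 3: 0.30, 4: 0.15}


@dataclass
class CohortConfig:
    """Full description of one synthetic cohort.

    Parameters
    ----------
    sites : list of :class:`SiteSpec`.
    images_per_woman_distribution : probabilities over repeat-image counts
        (default mean ~2.5, matching roughly 2.9 images/woman cohorts).
    class_mean_separation : spacing of adjacent class means along the
        severity axis, in feature units.
    within_woman_sd : sd of the woman-level random effect shared by all of
        a woman's images.
    between_image_sd : sd of the independent per-image noise.
    noise_corr : optional correlation between the severity axis (feature 0)
        and the first device-shift axis (feature 1) in both noise
        components; nonzero values make the optimal classifier lean on the
        shift axis, so a device translation then also biases its class
        calls (off by default).
    feature_noise_scales : optional per-feature multipliers applied to both
        noise components (None = all ones); embeddings rarely have
        homoscedastic coordinates, and a quieter coordinate is cheap for a
        classifier to exploit.
    """

    sites: list[SiteSpec]
    images_per_woman_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_IMAGES_PER_WOMAN)
    )
    class_mean_separation: float = 1.15
    within_woman_sd: float = 0.4
    between_image_sd: float = 0.5
    n_features: int = 8
    noise_corr: float = 0.0
    feature_noise_scales: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.images_per_woman_distribution.values()), dtype=float)
        counts = list(self.images_per_woman_distribution.keys())
        if len(probs) == 0 or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("images_per_woman_distribution must sum to 1")
        if np.any(probs < 0) or any(int(c) < 1 for c in counts):
            raise ConfigurationError("images_per_woman_distribution: counts >= 1, probs >= 0")
        if self.class_mean_separation <= 0:
            raise ConfigurationError("class_mean_separation must be > 0")
        if self.within_woman_sd <= 0 or self.between_image_sd <= 0:
            raise ConfigurationError("sd parameters must be > 0")
        if not -1.0 < self.noise_corr < 1.0:
            raise ConfigurationError("noise_corr must lie in (-1, 1)")
        if self.n_features < 2:
            raise ConfigurationError("need at least 2 features (severity + shift axis)")
        if self.feature_noise_scales is not None:
            scales = np.asarray(self.feature_noise_scales, dtype=float)
            if scales.shape != (self.n_features,) or np.any(scales <= 0):
                raise ConfigurationError(
                    "feature_noise_scales must be positive with one entry per feature"
                )
        for site in self.sites:
            site.validate(self.n_features)

    @property
    def gt_cin2_only_sites(self) -> tuple[str, ...]:
        return tuple(s.site_name for s in self.sites if s.gt_cin2_only)

    # -- YAML round trip (CLI surface) ------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_features": self.n_features,
            "class_mean_separation": self.class_mean_separation,
            "within_woman_sd": self.within_woman_sd,
            "between_image_sd": self.between_image_sd,
            "noise_corr": self.noise_corr,
            "feature_noise_scales": (
                None if self.feature_noise_scales is None
                else np.asarray(self.feature_noise_scales).tolist()
            ),
            "seed": self.seed,
            "images_per_woman_distribution": {
                int(k): float(v) for k, v in self.images_per_woman_distribution.items()
            },
            "sites": [
                {
                    "site_name": s.site_name,
                    "device": s.device,
                    "n_women_per_class": list(s.n_women_per_class),
                    "geo_shift": np.asarray(s.geo_shift).tolist(),
                    "device_shift": np.asarray(s.device_shift).tolist(),
                    "severity_axis": (
                        None if s.severity_axis is None
                        else np.asarray(s.severity_axis).tolist()
                    ),
                    "gt_cin2_only": s.gt_cin2_only,
                }
                for s in self.sites
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sites = [
            SiteSpec(
                site_name=s["site_name"],
                device=s["device"],
                n_women_per_class=tuple(s["n_women_per_class"]),
                geo_shift=np.asarray(s["geo_shift"], dtype=float),
                device_shift=np.asarray(s["device_shift"], dtype=float),
                severity_axis=(
                    None if s.get("severity_axis") is None
                    else np.asarray(s["severity_axis"], dtype=float)
                ),
                gt_cin2_only=bool(s.get("gt_cin2_only", False)),
            )
            for s in doc["sites"]
        ]
        cfg = cls(
            sites=sites,
            images_per_woman_distribution={
                int(k): float(v) for k, v in doc["images_per_woman_distribution"].items()
            },
            class_mean_separation=float(doc["class_mean_separation"]),
            within_woman_sd=float(doc["within_woman_sd"]),
            between_image_sd=float(doc["between_image_sd"]),
            n_features=int(doc["n_features"]),
            noise_corr=float(doc.get("noise_corr", 0.0)),
            feature_noise_scales=(
                None if doc.get("feature_noise_scales") is None
                else np.asarray(doc["feature_noise_scales"], dtype=float)
            ),
            seed=int(doc.get("seed", 0)),
        )
        cfg.validate()
        return cfg


@dataclass
class WomanRecord:
    """One woman: diagnostic facts plus her repeat-image feature vectors."""

    woman_id: str
    site: str
    device: str
    true_class: int
    histology: str
    hrhpv: str
    expert_label: str
    images: np.ndarray  # (n_images, n_features)

    def __post_init__(self) -> None:
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.images.shape[0] < 1:
            raise ValueError(f"woman {self.woman_id}: at least one image required")


def generate_diagnostic_facts(
    true_class: int,
    site: str,
    rng: np.random.Generator | int,
    gt_cin2_only: bool = False,
) -> tuple[str, str, str]:
    """Draw (histology, hrhpv, expert_label) consistent with ``true_class``.

    The draw inverts the ground-truth delineation rules, so running the
    rule engine on the returned facts recovers ``true_class`` exactly.
    Sites flagged ``gt_cin2_only`` only ever emit >CIN2 precancer+ records.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if true_class == PRECANCER:
        if gt_cin2_only:
            histology = rng.choice(["CIN3", "AIS", "cancer"], p=[0.75, 0.05, 0.20])
            return str(histology), "not_tested", "absent"
        if rng.random() < 0.7:  # definitive >=CIN3 confirmation
            histology = str(rng.choice(["CIN3", "AIS", "cancer"], p=[0.85, 0.05, 0.10]))
            hrhpv = str(rng.choice(["positive", "not_tested"], p=[0.8, 0.2]))
            return histology, hrhpv, "absent"
        return "CIN2", "positive", "absent"
    if true_class == INDETERMINATE:
        if gt_cin2_only:
            raise ConfigurationError(f"site {site!r} is >CIN2-only; cannot emit indeterminate")
        if rng.random() < 0.4:
            return "CIN2", "negative", "absent"
        histology = str(rng.choice(["lt_CIN2", "missing"], p=[0.7, 0.3]))
        hrhpv = str(rng.choice(["positive", "negative", "not_tested"], p=[0.3, 0.4, 0.3]))
        return histology, hrhpv, "indeterminate"
    if true_class == NORMAL:
        if gt_cin2_only:
            raise ConfigurationError(f"site {site!r} is >CIN2-only; cannot emit normal")
        histology = str(rng.choice(["lt_CIN2", "missing"], p=[0.6, 0.4]))
        hrhpv = str(rng.choice(["negative", "not_tested"], p=[0.7, 0.3]))
        return histology, hrhpv, "normal"
    raise ValueError(f"invalid class {true_class!r}")


def _noise_cholesky(n_features: int, noise_corr: float) -> np.ndarray:
    corr = np.eye(n_features)
    corr[0, 1] = corr[1, 0] = noise_corr
    return np.linalg.cholesky(corr)


def generate_cohort(config: CohortConfig) -> list[WomanRecord]:
    """Generate a full cohort; deterministic given ``config.seed``.

    Each image is drawn as

        class_mean + geo_shift + device_shift + woman_effect + image_noise

    with the class means at ``(c - 1) * class_mean_separation`` along the
    site's severity axis (feature 0 unless the site overrides it), the
    woman effect shared by all of a woman's images
    (sd = ``within_woman_sd``) and independent per-image noise
    (sd = ``between_image_sd``), both with correlation ``noise_corr``
    between features 0 and 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    chol = _noise_cholesky(d, config.noise_corr)
    scales = (
        np.ones(d)
        if config.feature_noise_scales is None
        else np.asarray(config.feature_noise_scales, dtype=float)
    )
    img_counts = np.array(sorted(config.images_per_woman_distribution), dtype=int)
    img_probs = np.array(
        [config.images_per_woman_distribution[int(k)] for k in img_counts], dtype=float
    )
    img_probs = img_probs / img_probs.sum()

    severity = np.zeros(d)
    severity[0] = 1.0

    cohort: list[WomanRecord] = []
    widx = 0
    for site in config.sites:
        base = np.asarray(site.geo_shift, float) + np.asarray(site.device_shift, float)
        axis = severity if site.severity_axis is None else np.asarray(site.severity_axis, float)
        for cls in (NORMAL, INDETERMINATE, PRECANCER):
            mean = base + (cls - 1) * config.class_mean_separation * axis
            for _ in range(site.n_women_per_class[cls]):
                woman_id = f"{site.site_name}-w{widx:05d}"
                widx += 1
                histology, hrhpv, expert = generate_diagnostic_facts(
                    cls, site.site_name, rng, gt_cin2_only=site.gt_cin2_only
                )
                n_img = int(rng.choice(img_counts, p=img_probs))
                woman_effect = config.within_woman_sd * scales * (chol @ rng.standard_normal(d))
                noise = config.between_image_sd * (rng.standard_normal((n_img, d)) @ chol.T) * scales
                images = mean + woman_effect + noise
                cohort.append(
                    WomanRecord(
                        woman_id=woman_id,
                        site=site.site_name,
                        device=site.device,
                        true_class=cls,
                        histology=histology,
                        hrhpv=hrhpv,
                        expert_label=expert,
                        images=images,
                    )
                )
    return cohort


# ---------------------------------------------------------------------------
# default study-structure configurations
# ---------------------------------------------------------------------------

#: EXT-style per-site (normal, indeterminate, precancer+) woman counts,
#: following the published six-country external-cohort breakdown
#: (totals 204 / 157 / 219 women = 580).
EXT_WOMEN_PER_CLASS: dict[str, tuple[int, int, int]] = {
    "Bolivia": (40, 33, 15),
    "Brazil": (0, 0, 154),
    "Cameroon": (85, 13, 2),
    "El Salvador": (49, 0, 21),
    "Kenya": (0, 109, 13),
    "Thailand": (30, 2, 14),
}

#: SEED-style studies mapped to their capture devices.
SEED_STUDY_DEVICES: dict[str, str] = {
    "NHS": "cerviscope",
    "ALTS": "cerviscope",
    "CVT": "cerviscope",
    "Biop": "DSLR",
    "DBiop": "DSLR",
}

DEVICE_SHIFT_MAGNITUDE = 3.0
GEO_SHIFT_MAGNITUDE = 0.5
#: rotation of the new device's severity axis away from the global one
EXT_SEVERITY_ROTATION_DEG = 42.0
DEFAULT_WITHIN_WOMAN_SD = 0.4
DEFAULT_BETWEEN_IMAGE_SD = 0.5
#: feature 3 (the axis the new device's severity signal rotates into) is a
#: quieter embedding coordinate, so a retrained model can recover the full
#: severity signal on the new device
DEFAULT_FEATURE_NOISE_SCALES = (1.0, 1.0, 1.0, 0.8, 1.0, 1.0, 1.0, 1.0)


def _unit(d: int, axis: int, sign: float = 1.0) -> np.ndarray:
    v = np.zeros(d)
    v[axis] = sign
    return v


def default_device_shifts(n_features: int = 8) -> dict[str, np.ndarray]:
    """Device cluster centres: large translations orthogonal to severity.

    The new-device (smartphone) shift points along the negative of the
    noise-correlated axis, which biases a model trained on the seed
    devices toward higher severity calls on the new device.
    """
    d = n_features
    return {
        "cerviscope": np.zeros(d),
        "DSLR": DEVICE_SHIFT_MAGNITUDE * _unit(d, 2),
        "J8": DEVICE_SHIFT_MAGNITUDE * _unit(d, 1, sign=-1.0),
    }


def ext_severity_axis(n_features: int = 8) -> np.ndarray:
    """Unit severity axis of the new device: the global axis rotated by
    ``EXT_SEVERITY_ROTATION_DEG`` into an otherwise signal-free feature."""
    theta = np.deg2rad(EXT_SEVERITY_ROTATION_DEG)
    axis = np.zeros(n_features)
    axis[0] = np.cos(theta)
    axis[3] = np.sin(theta)
    return axis


def default_seed_config(
    seed: int = 0,
    n_women_per_class_per_study: int = 100,
    n_features: int = 8,
) -> CohortConfig:
    """Multi-study, two-device seed cohort (~1500 women at defaults)."""
    dev_shifts = default_device_shifts(n_features)
    rng = np.random.default_rng(12345)  # fixed geometry, independent of cohort seed
    sites = []
    for i, (study, device) in enumerate(SEED_STUDY_DEVICES.items()):
        geo_dir = rng.standard_normal(n_features)
        geo_dir[:2] = 0.0  # keep geography off the severity/device-bias axes
        geo_dir /= np.linalg.norm(geo_dir)
        sites.append(
            SiteSpec(
                site_name=study,
                device=device,
                n_women_per_class=(n_women_per_class_per_study,) * 3,
                geo_shift=GEO_SHIFT_MAGNITUDE * geo_dir,
                device_shift=dev_shifts[device],
            )
        )
    return CohortConfig(
        sites=sites,
        n_features=n_features,
        feature_noise_scales=np.asarray(DEFAULT_FEATURE_NOISE_SCALES[:n_features]),
        seed=seed,
    )


def default_ext_config(
    seed: int = 1,
    n_features: int = 8,
    women_per_class: Mapping[str, tuple[int, int, int]] | None = None,
) -> CohortConfig:
    """Six-geography external cohort on one new device (580 women at defaults)."""
    dev_shifts = default_device_shifts(n_features)
    rng = np.random.default_rng(54321)
    sites = []
    counts = dict(EXT_WOMEN_PER_CLASS if women_per_class is None else women_per_class)
    for site_name, n_per_class in counts.items():
        geo_dir = rng.standard_normal(n_features)
        geo_dir[:2] = 0.0
        geo_dir /= np.linalg.norm(geo_dir)
        sites.append(
            SiteSpec(
                site_name=site_name,
                device="J8",
                n_women_per_class=tuple(n_per_class),
                geo_shift=GEO_SHIFT_MAGNITUDE * geo_dir,
                device_shift=dev_shifts["J8"],
                severity_axis=ext_severity_axis(n_features),
                gt_cin2_only=(site_name in DEFAULT_GT_CIN2_ONLY_SITES),
            )
        )
    return CohortConfig(
        sites=sites,
        n_features=n_features,
        feature_noise_scales=np.asarray(DEFAULT_FEATURE_NOISE_SCALES[:n_features]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def cohort_to_frames(cohort: Sequence[WomanRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (women, images) tables.

    ``women``: woman_id, site, device, true_class, histology, hrhpv,
    expert_label.  ``images``: image_id, woman_id, f1..fd.
    """
    women = pd.DataFrame(
        [
            {
                "woman_id": w.woman_id,
                "site": w.site,
                "device": w.device,
                "true_class": w.true_class,
                "histology": w.histology,
                "hrhpv": w.hrhpv,
                "expert_label": w.expert_label,
            }
            for w in cohort
        ],
        columns=[
            "woman_id", "site", "device", "true_class",
            "histology", "hrhpv", "expert_label",
        ],
    )
    img_rows = []
    for w in cohort:
        for j, feat in enumerate(w.images):
            img_rows.append(
                {"image_id": f"{w.woman_id}-i{j}", "woman_id": w.woman_id}
                | {f"f{k + 1}": feat[k] for k in range(len(feat))}
            )
    n_feat = cohort[0].images.shape[1] if len(cohort) else 0
    images = pd.DataFrame(
        img_rows, columns=["image_id", "woman_id"] + [f"f{k + 1}" for k in range(n_feat)]
    )
    return women, images


def frames_to_cohort(women: pd.DataFrame, images: pd.DataFrame) -> list[WomanRecord]:
    """Rebuild WomanRecords from the (women, images) tables."""
    feat_cols = [c for c in images.columns if c.startswith("f")]
    grouped = {wid: g[feat_cols].to_numpy(float) for wid, g in images.groupby("woman_id", sort=False)}
    cohort = []
    for row in women.itertuples(index=False):
        cohort.append(
            WomanRecord(
                woman_id=row.woman_id,
                site=row.site,
                device=row.device,
                true_class=int(row.true_class),
                histology=row.histology,
                hrhpv=row.hrhpv,
                expert_label=row.expert_label,
                images=grouped[row.woman_id],
            )
        )
    return cohort


def write_cohort(cohort: Sequence[WomanRecord], out_dir: str | Path) -> None:
    """Write women.csv, images.csv and a class-label sidecar mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    women, images = cohort_to_frames(cohort)
    women.to_csv(out / "women.csv", index=False)
    images.to_csv(out / "images.csv", index=False)
    (out / "class_labels.json").write_text(
        json.dumps({str(i): name for i, name in enumerate(CLASS_NAMES)}, indent=2) + "\n"
    )


def read_cohort(in_dir: str | Path) -> list[WomanRecord]:
    inp = Path(in_dir)
    women = pd.read_csv(inp / "women.csv")
    # round_trip: exact IEEE re-parse so write/read/write is byte-stable
    images = pd.read_csv(inp / "images.csv", float_precision="round_trip")
    return frames_to_cohort(women, images)


def subset(cohort: Sequence[WomanRecord], woman_ids: Sequence[str]) -> list[WomanRecord]:
    """Select women by id, preserving cohort order."""
    wanted = set(woman_ids)
    return [w for w in cohort if w.woman_id in wanted]


def stack_features(cohort: Sequence[WomanRecord]) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Flatten a cohort to (features, labels, image_ids, woman_ids) at image level."""
    feats, labels, image_ids, woman_ids = [], [], [], []
    for w in cohort:
        for j, f in enumerate(w.images):
            feats.append(f)
            labels.append(w.true_class)
            image_ids.append(f"{w.woman_id}-i{j}")
            woman_ids.append(w.woman_id)
    X = np.array(feats) if feats else np.empty((0, 0))
    return X, np.array(labels, dtype=int), image_ids, woman_ids
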