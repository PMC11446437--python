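"""Shared fixtures: small synthetic cohorts and experiment configs."""

from __future__ import annotations

import numpy as np
import pytest

from cervtriage.cohort import CohortConfig, SiteSpec, generate_cohort
from cervtriage.experiments import ExperimentConfig


def make_site(
    name: str,
    device: str,
    n_per_class=(5, 5, 5),
    d: int = 8,
    geo=None,
    dev=None,
    **kwargs,
) -> SiteSpec:
    return SiteSpec(
        site_name=name,
        device=device,
        n_women_per_class=tuple(n_per_class),
        geo_shift=np.zeros(d) if geo is None else np.asarray(geo, float),
        device_shift=np.zeros(d) if dev is None else np.asarray(dev, float),
        **kwargs,
    )


def two_device_config(n_per_class=(20, 20, 20), seed=0, shift_mag=3.0) -> CohortConfig:
    d = 8
    dev = np.zeros(d)
    dev[2] = shift_mag
    return CohortConfig(
        sites=[
            make_site("SiteA", "deviceA", n_per_class),
            make_site("SiteB", "deviceB", n_per_class, dev=dev),
        ],
        seed=seed,
    )


@pytest.fixture
def tiny_cohort():
    """Two-site, two-device cohort: 2x3x5 = 30 women."""
    return generate_cohort(two_device_config(n_per_class=(5, 5, 5), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_experiment_config(master_seed: int = 0, n_boot: int = 50) -> ExperimentConfig:
    """A complete but small experiment: runs in seconds."""
    d = 8
    dev_dslr = np.zeros(d)
    dev_dslr[2] = 3.0
    dev_j8 = np.zeros(d)
    dev_j8[1] = -3.0
    axis = np.zeros(d)
    axis[0], axis[3] = np.cos(0.7), np.sin(0.7)
    seed_cfg = CohortConfig(
        sites=[
            make_site("StudyA", "cerviscope", (25, 25, 25)),
            make_site("StudyB", "DSLR", (25, 25, 25), dev=dev_dslr),
        ],
        seed=100 + master_seed,
    )
    ext_cfg = CohortConfig(
        sites=[
            make_site("Bolivia", "J8", (8, 8, 8), dev=dev_j8, severity_axis=axis),
            make_site("SiteC", "J8", (10, 10, 10), dev=dev_j8, severity_axis=axis),
            make_site("SiteD", "J8", (6, 6, 6), dev=dev_j8, severity_axis=axis),
        ],
        seed=200 + master_seed,
    )
    return ExperimentConfig(
        seed_cohort_config=seed_cfg,
        ext_cohort_config=ext_cfg,
        heldout_geography="Bolivia",
        heldout_women_per_class=(10, 10, 12),
        increments=(0, 2, 5),
        ratios=((1, 1, 1), (2, 2, 1)),
        n_boot=n_boot,
        master_seed=master_seed,
    )
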