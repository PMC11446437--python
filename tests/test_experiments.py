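"""Experiment orchestration: splits, nesting, ratio accounting, panels."""

import json

import numpy as np
import pytest

from cervtriage.cohort import ConfigurationError, generate_cohort, stack_features
from cervtriage.experiments import (
    SamplingError,
    group_separation,
    heterogeneity_projection,
    model_panel,
    run_heterogeneity_suite,
    run_incremental_retraining,
    select_heldout,
    split_women_stratified,
)
from cervtriage.model import OrdinalTriageModel

from conftest import small_experiment_config, two_device_config


@pytest.fixture(scope="module")
def retrain_outputs():
    cfg = small_experiment_config(master_seed=0)
    return run_incremental_retraining(cfg)


class TestSplitsAndHeldout:
    def test_split_is_disjoint_and_stratified(self):
        cohort = generate_cohort(two_device_config(n_per_class=(20, 20, 20), seed=0))
        train, test = split_women_stratified(cohort, 0.25, seed=1)
        assert set(train).isdisjoint(test)
        assert len(train) + len(test) == len(cohort)
        cls = {w.woman_id: w.true_class for w in cohort}
        for c in range(3):
            assert sum(1 for w in test if cls[w] == c) == 10  # 0.25 of 40

    def test_heldout_counts_and_site_stratification(self):
        cfg = small_experiment_config()
        ext = generate_cohort(cfg.ext_cohort_config)
        ids = select_heldout(ext, (10, 10, 12), seed=3)
        cls = {w.woman_id: (w.true_class, w.site) for w in ext}
        got = [sum(1 for i in ids if cls[i][0] == c) for c in range(3)]
        assert got == [10, 10, 12]
        # every site contributes (proportional quotas over 3 sites)
        assert {cls[i][1] for i in ids} == {"Bolivia", "SiteC", "SiteD"}

    def test_heldout_request_beyond_pool_rejected(self):
        cfg = small_experiment_config()
        ext = generate_cohort(cfg.ext_cohort_config)
        with pytest.raises(SamplingError):
            select_heldout(ext, (1000, 0, 0), seed=0)


class TestHeterogeneitySuite:
    def test_missing_heldout_geography_rejected(self):
        cfg = small_experiment_config()
        cfg.heldout_geography = "Atlantis"
        with pytest.raises(ConfigurationError):
            run_heterogeneity_suite(cfg)

    def test_no_shift_null_runs_are_statistically_indistinguishable(self):
        """With zero device and geography shift and a common severity axis,
        the three runs' AUROC confidence intervals all overlap."""
        cfg = small_experiment_config(n_boot=100)
        for cc in (cfg.seed_cohort_config, cfg.ext_cohort_config):
            for i, s in enumerate(cc.sites):
                cc.sites[i] = type(s)(
                    site_name=s.site_name,
                    device=s.device,
                    n_women_per_class=s.n_women_per_class,
                    geo_shift=np.zeros_like(s.geo_shift),
                    device_shift=np.zeros_like(s.device_shift),
                    severity_axis=None,
                    gt_cin2_only=s.gt_cin2_only,
                )
        runs, _ = run_heterogeneity_suite(cfg)
        i, ii, iii = (runs[k].metrics for k in ("seed_test", "ext_oob", "geo_holdout"))
        assert i.auroc_normal_vs_rest.overlaps(ii.auroc_normal_vs_rest)
        assert i.auroc_precancer_vs_rest.overlaps(ii.auroc_precancer_vs_rest)
        assert i.auroc_normal_vs_rest.overlaps(iii.auroc_normal_vs_rest)
        assert i.auroc_precancer_vs_rest.overlaps(iii.auroc_precancer_vs_rest)

    def test_deterministic_given_master_seed(self):
        cfg = small_experiment_config(n_boot=30)
        a, man_a = run_heterogeneity_suite(cfg)
        b, man_b = run_heterogeneity_suite(small_experiment_config(n_boot=30))
        dump = lambda runs: json.dumps({k: r.to_json_dict() for k, r in runs.items()})
        assert dump(a) == dump(b)
        assert json.dumps(man_a) == json.dumps(man_b)


class TestIncrementalRetraining:
    def test_zero_increment_equals_out_of_the_box(self, retrain_outputs):
        curves, _ = retrain_outputs
        rows0 = [curve.rows[0] for curve in curves.values()]
        # both ratio arms share the identical baseline at n=0
        a, b = rows0
        assert a.ext_metrics.auroc_normal_vs_rest == b.ext_metrics.auroc_normal_vs_rest
        assert np.array_equal(a.ext_metrics.confusion, b.ext_metrics.confusion)
        assert a.women_added_total == 0

    def test_increments_are_nested_within_each_ratio(self, retrain_outputs):
        curves, _ = retrain_outputs
        for curve in curves.values():
            previous = set()
            for row in curve.rows:
                current = set(row.added_woman_ids)
                assert previous <= current
                previous = current

    def test_ratio_accounting_is_exact(self, retrain_outputs):
        curves, _ = retrain_outputs
        for ratio, curve in curves.items():
            for row in curve.rows:
                n = row.n_added
                assert row.women_added_per_class == tuple(r * n for r in ratio)
                assert row.women_added_total == sum(ratio) * n
                assert len(row.added_woman_ids) == sum(ratio) * n

    def test_heldout_test_set_fixed_across_increments_and_ratios(self, retrain_outputs):
        curves, manifest = retrain_outputs
        n_images = {
            row.ext_metrics.n_images for curve in curves.values() for row in curve.rows
        }
        assert n_images == {manifest["n_heldout_images"]}
        heldout = set(manifest["heldout_woman_ids"])
        for curve in curves.values():
            for row in curve.rows:
                assert heldout.isdisjoint(row.added_woman_ids)

    def test_insufficient_pool_raises_with_deficient_class(self):
        cfg = small_experiment_config()
        cfg.increments = (0, 50)  # far beyond the 14/14/12 pool
        with pytest.raises(SamplingError, match="class"):
            run_incremental_retraining(cfg)

    def test_curve_frame_has_one_row_per_increment(self, retrain_outputs):
        curves, _ = retrain_outputs
        for curve in curves.values():
            frame = curve.as_frame()
            assert list(frame["n_added"]) == [0, 2, 5]
            assert frame["ext_loa_width"].notna().all()


@pytest.fixture(scope="module")
def panel_inputs():
    cohort = generate_cohort(two_device_config(n_per_class=(10, 10, 10), seed=3))
    X, y, image_ids, _ = stack_features(cohort)
    models = [OrdinalTriageModel.from_cohort(cohort).fit(seed=s) for s in (0, 1)]
    return models, X, y, image_ids


class TestModelPanel:
    def test_requested_rows_per_class(self, panel_inputs):
        models, X, y, ids = panel_inputs
        panel = model_panel(models, X, y, ids, per_class=5, seed=0)
        assert (panel.groupby("true_class").size() == 5).all()
        assert {"model_0", "model_1"} <= set(panel.columns)

    def test_full_selection_is_sorted_within_class(self, panel_inputs):
        models, X, y, ids = panel_inputs
        n_min = min(np.bincount(y))
        panel = model_panel(models, X, y, ids, per_class=n_min, seed=0)
        for _, g in panel.groupby("true_class"):
            assert g["mean_score"].is_monotonic_increasing

    def test_single_model_panel_uses_its_own_scores(self, panel_inputs):
        models, X, y, ids = panel_inputs
        panel = model_panel(models[:1], X, y, ids, per_class=4, seed=0)
        own = models[0].predict(X, image_ids=ids).set_index("image_id")["score"]
        assert np.allclose(panel["mean_score"], own.loc[panel["image_id"]].to_numpy())

    def test_oversized_request_rejected(self, panel_inputs):
        models, X, y, ids = panel_inputs
        with pytest.raises(ValueError):
            model_panel(models, X, y, ids, per_class=10_000)


class TestHeterogeneityProjection:
    def test_well_separated_groups_score_high(self, rng):
        a = rng.normal(0, 0.3, size=(100, 6))
        b = rng.normal(8, 0.3, size=(100, 6))
        X = np.vstack([a, b])
        labels = ["a"] * 100 + ["b"] * 100
        rep = heterogeneity_projection(X, {"group": labels})
        assert rep.separation["group"] > 0.8
        assert rep.embedding.shape == (200, 2)

    def test_identical_distributions_score_near_zero(self, rng):
        X = rng.normal(size=(200, 6))
        labels = ["a"] * 100 + ["b"] * 100
        rep = heterogeneity_projection(X, {"group": labels})
        assert abs(rep.separation["group"]) < 0.15

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_separation(rng.normal(size=(10, 2)), ["a"] * 10)

    def test_device_separation_exceeds_geography_separation(self):
        cfg = small_experiment_config()
        seed_cohort = generate_cohort(cfg.seed_cohort_config)
        ext_cohort = generate_cohort(cfg.ext_cohort_config)
        X, _, _, _ = stack_features(seed_cohort + ext_cohort)
        devices = [w.device for w in seed_cohort + ext_cohort for _ in w.images]
        dev_sep = heterogeneity_projection(X, {"device": devices}).separation["device"]
        ext_X, _, _, _ = stack_features(ext_cohort)
        geos = [w.site for w in ext_cohort for _ in w.images]
        geo_sep = heterogeneity_projection(ext_X, {"geo": geos}).separation["geo"]
        assert dev_sep > geo_sep
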