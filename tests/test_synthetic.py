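"""Phantom cohort generator and prediction degradation model."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nodeval import (
    CohortConfig,
    DegradationConfig,
    EvalConfig,
    compare_groups_kw,
    degrade_to_prediction,
    expected_metrics,
    extract_instances,
    iter_cohort,
    sample_gt_scan,
)
from nodeval.pipeline import evaluate_scan

SMALL = dict(grid_shape=(96, 96, 48), nodes_per_scan_mean=8.0)


class TestCohortConfig:
    def test_lognormal_calibration_reproduces_status_means(self):
        cfg = CohortConfig()
        from scipy import stats as ss

        for metastatic, target_mean in ((False, 5.0), (True, 11.3)):
            mu, sigma, lo, hi = cfg.sad_params(metastatic)
            dist = ss.lognorm(s=sigma, scale=np.exp(mu))
            u = np.linspace(dist.cdf(lo), dist.cdf(hi), 20001)[1:-1]
            mean = dist.ppf(u).mean()
            assert mean == pytest.approx(target_mean, rel=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_scans=0)
        with pytest.raises(ValueError):
            CohortConfig(metastatic_fraction=1.5)
        with pytest.raises(ValueError):
            DegradationConfig(miss_probabilities=(0.5, 0.5))

    def test_round_trip(self):
        cfg = CohortConfig(n_scans=3, seed=7)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg
        dcfg = DegradationConfig(fp_rate=2.0)
        assert DegradationConfig.from_dict(dcfg.to_dict()) == dcfg


class TestSampleGtScan:
    def test_single_node_hits_target_sad(self):
        cfg = CohortConfig(
            n_scans=1, nodes_per_scan_mean=1, grid_shape=(64, 64, 32),
            spacing=(1.0, 1.0, 1.0), sad_distribution="stratified",
            stratified_ranges=((10.0, 10.0001),) * 4, cluster_probability=0.0,
        )
        ph = sample_gt_scan(cfg, 11)
        assert len(ph.nodes) >= 1
        assert all(abs(s - 10.0) <= 1.0 for s in ph.nodes["sad_mm"])

    def test_forced_cluster_merges_into_one_instance(self):
        cfg = CohortConfig(
            n_scans=1, nodes_per_scan_mean=2, cluster_probability=1.0,
            sad_distribution="stratified", grid_shape=(96, 96, 48),
            stratified_ranges=((6.0, 12.0),) * 4
        )
        for seed in range(3):
            ph = sample_gt_scan(cfg, seed)
            # every companion shares a connected component with its partner
            _, nodes = extract_instances(ph.gt)
            assert len(nodes) < max(2, len(ph.nodes) + 1) or len(ph.nodes) == 1

    def test_seeded_regeneration_is_byte_identical(self):
        cfg = CohortConfig(n_scans=1, seed=5, **SMALL)
        a = sample_gt_scan(cfg, 42)
        b = sample_gt_scan(cfg, 42)
        np.testing.assert_array_equal(a.gt.voxels, b.gt.voxels)
        assert a.nodes.equals(b.nodes)

    def test_grid_too_small_raises(self):
        cfg = CohortConfig(
            n_scans=1, nodes_per_scan_mean=60, grid_shape=(24, 24, 10),
            sad_distribution="stratified",
        )
        with pytest.raises(RuntimeError, match="place"):
            sample_gt_scan(cfg, 0)

    def test_necrotic_cores_only_in_large_metastatic_nodes(self):
        cfg = CohortConfig(
            n_scans=1, nodes_per_scan_mean=6, metastatic_fraction=1.0,
            sad_distribution="stratified",
            stratified_ranges=((16.0, 22.0),) * 4, grid_shape=(128, 128, 64),
            cluster_probability=0.0,
        )
        ph = sample_gt_scan(cfg, 9)
        assert ph.nodes["necrotic"].all()
        assert ph.necrosis_core.any()
        # cores are node tissue: strictly inside the ground truth
        assert not (ph.necrosis_core & ~ph.gt.foreground()).any()


class TestDegradation:
    def _phantom(self, seed=1, **over):
        cfg = CohortConfig(n_scans=1, cluster_probability=0.0, **{**SMALL, **over})
        return sample_gt_scan(cfg, seed)

    def test_identity_degradation_reproduces_gt(self):
        ph = self._phantom()
        dcfg = DegradationConfig(
            miss_probabilities=(0, 0, 0, 0), dilation_probability=0,
            erosion_probability=0, necrosis_dropout_probability=0, fp_rate=0,
        )
        pred = degrade_to_prediction(ph, dcfg, 2)
        np.testing.assert_array_equal(pred.voxels, ph.gt.voxels)
        ev = evaluate_scan(ph.gt, pred, EvalConfig(min_pred_sad_mm=0.0))
        assert ev.metrics["recall"] == 1.0
        assert ev.metrics["global_dice"] == 1.0
        assert ev.metrics["fps"] == 0

    def test_total_miss_empties_prediction(self):
        ph = self._phantom()
        dcfg = DegradationConfig(miss_probabilities=(1, 1, 1, 1), fp_rate=0)
        pred = degrade_to_prediction(ph, dcfg, 3)
        assert pred.voxels.sum() == 0

    def test_fp_rate_matches_poisson_mean(self):
        cfg = CohortConfig(
            n_scans=40, nodes_per_scan_mean=3, grid_shape=(96, 96, 48),
            cluster_probability=0.0, seed=8,
        )
        dcfg = DegradationConfig(
            miss_probabilities=(1, 1, 1, 1), dilation_probability=0,
            erosion_probability=0, fp_rate=6.5,
        )
        counts = []
        for ph, pred in iter_cohort(cfg, dcfg):
            _, fps = extract_instances(pred)
            counts.append(len(fps))
        mean = np.mean(counts)
        se = np.sqrt(6.5 / len(counts))
        assert abs(mean - 6.5) <= 3 * se

    def test_erosion_monotonically_lowers_sensitivity_and_dice(self):
        ph = self._phantom(seed=4, nodes_per_scan_mean=6)
        results = []
        for radius in (0, 1, 2):
            dcfg = DegradationConfig(
                miss_probabilities=(0, 0, 0, 0),
                dilation_probability=0.0,
                erosion_probability=1.0 if radius else 0.0,
                erosion_radius=radius or 1,
                erosion_min_sad_mm=0.0,
                necrosis_dropout_probability=0.0,
                fp_rate=0,
            )
            pred = degrade_to_prediction(ph, dcfg, 7)
            ev = evaluate_scan(ph.gt, pred, EvalConfig(min_pred_sad_mm=0.0))
            results.append(
                (ev.gt_nodes["sensitivity"].mean(), ev.metrics["global_dice"])
            )
        sens = [r[0] for r in results]
        dice = [r[1] for r in results]
        assert sens[0] > sens[1] > sens[2]
        assert dice[0] > dice[1] > dice[2]

    def test_necrosis_dropout_hits_only_large_metastatic_nodes(self):
        cfg = CohortConfig(
            n_scans=1, nodes_per_scan_mean=10, metastatic_fraction=1.0,
            sad_distribution="stratified", cluster_probability=0.0,
            grid_shape=(150, 150, 60),
        )
        ph = sample_gt_scan(cfg, 21)
        base = DegradationConfig(
            miss_probabilities=(0, 0, 0, 0), dilation_probability=0,
            erosion_probability=0, necrosis_dropout_probability=0.0, fp_rate=0,
        )
        drop = dataclasses.replace(base, necrosis_dropout_probability=1.0)
        ev0 = evaluate_scan(ph.gt, degrade_to_prediction(ph, base, 5),
                            EvalConfig(min_pred_sad_mm=0.0))
        ev1 = evaluate_scan(ph.gt, degrade_to_prediction(ph, drop, 5),
                            EvalConfig(min_pred_sad_mm=0.0))
        merged = ev0.gt_nodes.merge(ev1.gt_nodes, on="node_id", suffixes=("_0", "_1"))
        large = merged[merged["sad_mm_0"] >= 15]
        small = merged[merged["sad_mm_0"] < 10]
        assert len(large) and len(small)
        assert (large["sensitivity_1"] < large["sensitivity_0"]).all()
        assert (small["sensitivity_1"] == small["sensitivity_0"]).all()


class TestCohortStructure:
    def test_status_size_difference_is_detected(self):
        cfg = CohortConfig(n_scans=8, seed=13)
        sads = {"mets": [], "non-mets": []}
        for ph, _ in iter_cohort(cfg, None):
            for row in ph.nodes.itertuples():
                sads["mets" if row.metastatic else "non-mets"].append(row.sad_mm)
        res = compare_groups_kw(sads, alpha=0.01)
        assert res.significant
        assert np.mean(sads["mets"]) > np.mean(sads["non-mets"])

    def test_expected_metrics_are_complements(self):
        cfg = CohortConfig()
        dcfg = DegradationConfig()
        exp = expected_metrics(cfg, dcfg)
        assert exp["recall_per_bin"] == {
            "<5": pytest.approx(0.72), "5–10": pytest.approx(0.79),
            "10–15": pytest.approx(0.67), ">15": pytest.approx(0.36),
        }
        assert exp["fps_per_scan"] == 6.5
        zero = DegradationConfig(miss_probabilities=(0, 0, 0, 0), fp_rate=0)
        exp0 = expected_metrics(cfg, zero)
        assert all(v == 1.0 for v in exp0["recall_per_bin"].values())
        assert exp0["fps_per_scan"] == 0
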