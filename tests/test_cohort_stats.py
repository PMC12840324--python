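"""Cohort aggregation, stratified tables and nonparametric statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nodeval import (
    aggregate_cohort,
    compare_groups_kw,
    normality_screen,
    posthoc_pairwise,
    sad_sensitivity_correlation,
    stratified_table,
)
from nodeval import calibration

from oracles import kruskal_h


def _node_table(rows):
    return pd.DataFrame(
        rows, columns=["scan_id", "sad_mm", "sad_bin", "metastatic", "sensitivity", "localized"]
    )


class TestStratifiedTable:
    def test_counts_sum_across_status_and_bins(self, rng):
        bins = ["<5", "5–10", "10–15", ">15"]
        rows = []
        for i in range(300):
            b = bins[rng.integers(4)]
            rows.append(
                (f"s{i%10}", rng.uniform(2, 30), b, bool(rng.integers(2)),
                 rng.uniform(), bool(rng.integers(2)))
            )
        table = stratified_table(_node_table(rows))
        n = table.loc["n_nodes"]
        for col in table.columns:
            assert n.loc["all", col] == n.loc["non-mets", col] + n.loc["mets", col]
        assert n.loc["all", "All"] == sum(n.loc["all", b] for b in bins) == 300

    def test_empty_stratum_is_missing_not_zero(self):
        rows = [("s0", 6.0, "5–10", False, 0.9, True)]
        table = stratified_table(_node_table(rows))
        assert np.isnan(table.loc[("sensitivity", "mets"), ">15"])
        assert table.loc[("n_nodes", "mets"), ">15"] == 0


class TestAggregateCohort:
    def _cohort(self, scans):
        metrics, rows = {}, []
        for sid, nodes in scans.items():
            loc = [l for _, l in nodes]
            metrics[sid] = {
                "recall": sum(loc) / len(loc), "precision": 1.0, "f1": 1.0,
                "fps": 0, "fp_sads_mm": [], "n_gt": len(loc), "n_pred": len(loc),
            }
            for sens, l in nodes:
                rows.append((sid, 6.0, "5–10", False, sens, l))
        return metrics, _node_table(rows)

    def test_macro_vs_micro_recall(self):
        scans = {
            "a": [(1.0, True), (1.0, True)],  # recall 1.0, 2 nodes
            "b": [(0.0, False)] * 8,  # recall 0.0, 8 nodes
        }
        metrics, nodes = self._cohort(scans)
        rep = aggregate_cohort(metrics, nodes)
        assert rep.cohort_recall_macro == pytest.approx(0.5)
        assert rep.cohort_recall_micro == pytest.approx(0.2)

    def test_single_perfect_scan(self):
        metrics, nodes = self._cohort({"a": [(1.0, True)] * 5})
        rep = aggregate_cohort(metrics, nodes)
        assert rep.cohort_recall_macro == rep.cohort_recall_micro == 1.0

    def test_micro_recall_equals_weighted_bin_recalls(self, rng):
        rows = []
        bins = ["<5", "5–10", "10–15", ">15"]
        for i in range(400):
            rows.append(
                (f"s{i%20}", rng.uniform(2, 30), bins[rng.integers(4)],
                 bool(rng.integers(2)), rng.uniform(), bool(rng.integers(2)))
            )
        nodes = _node_table(rows)
        metrics = {
            sid: {"recall": g["localized"].mean(), "precision": 1.0, "f1": 1.0,
                  "fps": 0, "fp_sads_mm": [], "n_gt": len(g), "n_pred": len(g)}
            for sid, g in nodes.groupby("scan_id")
        }
        rep = aggregate_cohort(metrics, nodes)
        counts = [rep.strata.loc[("n_nodes", "all"), b] for b in bins]
        recalls = [rep.strata.loc[("recall", "all"), b] for b in bins]
        weighted = calibration.pooled_recall(counts, recalls)
        assert rep.cohort_recall_micro == pytest.approx(weighted, abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_cohort({}, _node_table([]))


class TestKruskalWallis:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(size=50)
        res = compare_groups_kw({"a": vals, "b": vals.copy()})
        assert res.p_value > 0.9 and not res.significant

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(8, 1, 100)
        res = compare_groups_kw({"a": a, "b": b}, alpha=0.01)
        assert res.significant

    def test_matches_textbook_h_on_small_tiefree_sample(self):
        groups = {"g1": [1.0, 4.0, 7.0], "g2": [2.0, 5.0, 8.0], "g3": [3.0, 6.0, 9.0]}
        res = compare_groups_kw(groups)
        expected_h = kruskal_h([np.array(v) for v in groups.values()])
        assert res.statistic == pytest.approx(expected_h)

    def test_constant_data_reports_no_difference(self):
        res = compare_groups_kw({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_tiny_group_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = compare_groups_kw({"a": [1.0], "b": [1.0, 2.0]})
        assert res is None

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_kw({"a": [1, 2, 3]})


class TestPosthocPairwise:
    def test_identical_groups_nothing_significant(self, rng):
        base = rng.normal(size=40)
        groups = {k: base + rng.normal(0, 1e-3, 40) for k in "abcd"}
        results = posthoc_pairwise(groups, alpha=0.01)
        assert len(results) == 6
        assert not any(r.significant for r in results)

    def test_single_shifted_group_flagged_in_its_pairs_only(self, rng):
        groups = {k: rng.normal(0, 1, 80) for k in "abc"}
        groups["d"] = rng.normal(10, 1, 80)
        results = posthoc_pairwise(groups, alpha=0.01)
        for r in results:
            assert r.significant == ("d" in r.groups)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            posthoc_pairwise({"a": [1, 2], "b": [3, 4]})

    def test_holm_adjustment_is_monotone_and_larger(self, rng):
        groups = {k: rng.normal(i, 1, 30) for i, k in enumerate("abcd")}
        raw = posthoc_pairwise(groups)
        holm = posthoc_pairwise(groups, correction="holm")
        for r, h in zip(raw, holm):
            assert h.p_value >= r.p_value - 1e-15


class TestNormalityScreen:
    def test_uniform_draws_flagged_non_normal(self, rng):
        res = normality_screen(rng.uniform(0, 1, 500))
        assert res.p_value < 0.01

    def test_normal_draws_pass(self, rng):
        res = normality_screen(rng.normal(0, 1, 500))
        assert res.p_value > 0.01

    def test_constant_vector_is_degenerate(self):
        res = normality_screen([2.0] * 10)
        assert np.isnan(res.p_value) and res.note == "constant input"

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])

    def test_large_sample_subsampled_deterministically(self, rng):
        vals = rng.normal(size=8000)
        r1 = normality_screen(vals)
        r2 = normality_screen(vals)
        assert r1.statistic == r2.statistic and "subsample" in r1.note


class TestSadSensitivityCorrelation:
    def _table(self, sad, sens):
        return pd.DataFrame({"sad_mm": sad, "sensitivity": sens})

    def test_perfect_negative_relation(self):
        sad = np.linspace(5, 30, 20)
        res = sad_sensitivity_correlation(self._table(sad, 1 - sad / 40))
        assert res.statistic == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self, rng):
        res = sad_sensitivity_correlation(
            self._table(rng.uniform(3, 30, 1000), rng.uniform(0, 1, 1000))
        )
        assert abs(res.statistic) < 0.1

    def test_sad_min_restricts_the_sample(self):
        sad = np.array([5.0, 8.0, 12.0, 20.0, 30.0, 40.0])
        sens = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        res = sad_sensitivity_correlation(self._table(sad, sens), sad_min=10.0)
        assert res.n_per_group == (4,)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sad_sensitivity_correlation(self._table([5, 5, 5], [0.1, 0.2, 0.3]))


class TestReferenceArithmetic:
    def test_pooled_recall_reproduces_reference_rows(self):
        all_pooled = calibration.pooled_recall(
            calibration.NODE_COUNTS["all"], calibration.BIN_RECALLS["all"]
        )
        nonmets = calibration.pooled_recall(
            calibration.NODE_COUNTS["non-mets"], calibration.BIN_RECALLS["non-mets"]
        )
        assert f"{all_pooled:.2f}" == "0.73"
        assert f"{nonmets:.2f}" == "0.74"
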