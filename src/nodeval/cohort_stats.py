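"""Cohort aggregation: size/status-stratified tables and group statistics.

Aggregates per-scan evaluation output into a cohort report shaped like a
stratified detection table (node counts, recall and mean per-node
sensitivity by SAD stratum and nodal status) plus the nonparametric group
comparisons: Shapiro–Wilk normality screen, Kruskal–Wallis across groups
at alpha = 0.01, post hoc pairwise rank tests, and the Pearson correlation
between node SAD and per-node sensitivity.

Two recall conventions are reported side by side and labelled explicitly,
because they differ whenever scans carry unequal node counts:

* macro recall — the mean of per-scan recalls;
* micro recall — localized nodes pooled over the whole cohort divided by
  all nodes, identical to the node-count-weighted mean of stratum recalls.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import StatResult
from .morphometry import sad_bin_labels

logger = logging.getLogger(__name__)

__all__ = [
    "CohortReport",
    "aggregate_cohort",
    "stratified_table",
    "compare_groups_kw",
    "posthoc_pairwise",
    "normality_screen",
    "sad_sensitivity_correlation",
]

_STATUS_ROWS = ("all", "non-mets", "mets")


@dataclass
class CohortReport:
    """Stratified cohort summary plus statistical test results."""

    strata: pd.DataFrame  # index (measure, status), columns bins + "All"
    cohort_recall_macro: float
    cohort_recall_micro: float
    fps_per_scan_mean: float
    fp_mean_sad_mm: Optional[float]
    fp_large_per_scan: float  # FPs with SAD >= 10 mm per scan
    n_scans: int
    n_nodes: int
    mean_dice: Optional[float]
    mean_avg_hausdorff_mm: Optional[float]
    stats: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _stat(v):
            if isinstance(v, StatResult):
                return v.to_dict()
            if isinstance(v, list):
                return [_stat(x) for x in v]
            return v

        return {
            "strata": {
                f"{measure}|{status}": {
                    col: (None if pd.isna(val) else float(val))
                    for col, val in row.items()
                }
                for (measure, status), row in self.strata.iterrows()
            },
            "cohort_recall_macro": self.cohort_recall_macro,
            "cohort_recall_micro": self.cohort_recall_micro,
            "fps_per_scan_mean": self.fps_per_scan_mean,
            "fp_mean_sad_mm": self.fp_mean_sad_mm,
            "fp_large_per_scan": self.fp_large_per_scan,
            "n_scans": self.n_scans,
            "n_nodes": self.n_nodes,
            "mean_dice": self.mean_dice,
            "mean_avg_hausdorff_mm": self.mean_avg_hausdorff_mm,
            "stats": {k: _stat(v) for k, v in self.stats.items()},
        }


def stratified_table(
    nodes: pd.DataFrame, bin_edges: Sequence[float] = (5.0, 10.0, 15.0)
) -> pd.DataFrame:
    """Counts, recall and mean sensitivity by SAD stratum and status.

    ``nodes`` needs columns ``sad_bin, metastatic, localized, sensitivity``.
    Cells with no nodes are NaN (rendered as missing, never as zero).
    """
    bins = sad_bin_labels(bin_edges)
    columns = list(bins) + ["All"]
    index = pd.MultiIndex.from_product(
        [("n_nodes", "recall", "sensitivity"), _STATUS_ROWS],
        names=["measure", "status"],
    )
    table = pd.DataFrame(np.nan, index=index, columns=columns)
    subsets = {
        "all": nodes,
        "non-mets": nodes[~nodes["metastatic"].astype(bool)],
        "mets": nodes[nodes["metastatic"].astype(bool)],
    }
    for status, sub in subsets.items():
        for col in columns:
            part = sub if col == "All" else sub[sub["sad_bin"] == col]
            table.loc[("n_nodes", status), col] = len(part)
            if len(part):
                table.loc[("recall", status), col] = part["localized"].mean()
                table.loc[("sensitivity", status), col] = part["sensitivity"].mean()
    return table


def compare_groups_kw(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.01
) -> Optional[StatResult]:
    """Kruskal–Wallis H test across ≥2 groups of observations.

    Groups with fewer than 2 observations void the test (warning, returns
    ``None``).  When every observation is identical across all groups the
    H statistic is 0 and p is reported as 1 (no evidence of a difference).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(a) < 2 for a in arrays):
        logger.warning("group with < 2 observations; Kruskal–Wallis skipped")
        return None
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return StatResult(
            test_name="kruskal-wallis",
            statistic=0.0,
            p_value=1.0,
            groups=tuple(names),
            alpha=alpha,
            n_per_group=tuple(len(a) for a in arrays),
            note="all observations identical",
        )
    h, p = stats.kruskal(*arrays)
    return StatResult(
        test_name="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        groups=tuple(names),
        alpha=alpha,
        n_per_group=tuple(len(a) for a in arrays),
    )


def posthoc_pairwise(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    correction: Optional[str] = None,
) -> list[StatResult]:
    """All pairwise two-group rank comparisons after a global test.

    Each pair is compared with the two-sample Kruskal–Wallis test (the
    rank analogue of the pairwise comparison).  Raw p-values are reported
    by default; ``correction="holm"`` applies Holm step-down adjustment.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("post hoc comparisons need at least 3 groups; use compare_groups_kw")
    results: list[StatResult] = []
    for a, b in itertools.combinations(names, 2):
        res = compare_groups_kw({a: groups[a], b: groups[b]}, alpha=alpha)
        if res is not None:
            results.append(res)
    if correction == "holm":
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        running = 0.0
        adjusted = [0.0] * m
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * results[idx].p_value))
            adjusted[idx] = running
        results = [
            StatResult(
                test_name=r.test_name,
                statistic=r.statistic,
                p_value=adj,
                groups=r.groups,
                alpha=r.alpha,
                n_per_group=r.n_per_group,
                note="holm-adjusted",
            )
            for r, adj in zip(results, adjusted)
        ]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return results


def normality_screen(values: Sequence[float], alpha: float = 0.01) -> StatResult:
    """Shapiro–Wilk normality test.

    Requires n >= 3.  For n > 5000 a deterministic evenly-strided
    subsample of 5000 values is used (the test saturates there anyway).
    A constant vector is reported with W = 1 and p = NaN (undefined).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    note = ""
    if arr.size > 5000:
        idx = np.linspace(0, arr.size - 1, 5000).astype(int)
        arr = np.sort(arr)[idx]
        note = "strided subsample of 5000"
    if np.all(arr == arr[0]):
        return StatResult(
            test_name="shapiro-wilk", statistic=1.0, p_value=float("nan"),
            alpha=alpha, n_per_group=(int(arr.size),), note="constant input",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(arr)
    return StatResult(
        test_name="shapiro-wilk", statistic=float(w), p_value=float(p),
        alpha=alpha, n_per_group=(int(arr.size),), note=note,
    )


def sad_sensitivity_correlation(
    nodes: pd.DataFrame, sad_min: Optional[float] = None, alpha: float = 0.01
) -> StatResult:
    """Pearson correlation between node SAD and per-node sensitivity.

    ``sad_min`` restricts the computation to nodes with ``sad_mm > sad_min``
    (e.g. 10 to look at clearly measurable nodes only).
    """
    sub = nodes
    if sad_min is not None:
        sub = nodes[nodes["sad_mm"] > sad_min]
    if len(sub) < 3:
        raise ValueError("need at least 3 nodes for a correlation")
    x = sub["sad_mm"].to_numpy(dtype=float)
    y = sub["sensitivity"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in SAD or sensitivity")
    r, p = stats.pearsonr(x, y)
    label = "all nodes" if sad_min is None else f"sad > {sad_min:g} mm"
    return StatResult(
        test_name="pearson",
        statistic=float(r),
        p_value=float(p),
        groups=(label,),
        alpha=alpha,
        n_per_group=(len(sub),),
    )


def aggregate_cohort(
    scan_metrics: Mapping[str, dict],
    nodes: pd.DataFrame,
    bin_edges: Sequence[float] = (5.0, 10.0, 15.0),
    alpha: float = 0.01,
    recall_test_unit: str = "node",
    posthoc_correction: Optional[str] = None,
) -> CohortReport:
    """Cohort report from per-scan metric dicts and the pooled node table.

    ``scan_metrics`` maps scan_id -> the dict from
    :func:`nodeval.matching.scan_detection_metrics` (optionally extended
    with ``global_dice`` / ``avg_hausdorff_mm``); ``nodes`` is the pooled
    per-node table with columns ``scan_id, sad_mm, sad_bin, metastatic,
    sensitivity, localized``.
    """
    if not scan_metrics:
        raise ValueError("empty cohort")
    table = stratified_table(nodes, bin_edges)

    per_scan_recalls = [
        m["recall"] for m in scan_metrics.values() if m.get("recall") is not None
    ]
    macro = float(np.mean(per_scan_recalls)) if per_scan_recalls else float("nan")
    micro = float(nodes["localized"].mean()) if len(nodes) else float("nan")

    fps = [m["fps"] for m in scan_metrics.values()]
    fp_sads = [s for m in scan_metrics.values() for s in m.get("fp_sads_mm", [])]
    n_scans = len(scan_metrics)
    dices = [m["global_dice"] for m in scan_metrics.values() if m.get("global_dice") is not None]
    ahds = [
        m["avg_hausdorff_mm"]
        for m in scan_metrics.values()
        if m.get("avg_hausdorff_mm") is not None
    ]

    results: dict[str, object] = {
        "unit_of_analysis": recall_test_unit,
        "posthoc_correction": posthoc_correction or "none",
    }
    status = nodes["metastatic"].astype(bool)
    if recall_test_unit == "node":
        recall_groups = {
            "non-mets": nodes.loc[~status, "localized"].astype(float).to_numpy(),
            "mets": nodes.loc[status, "localized"].astype(float).to_numpy(),
        }
    elif recall_test_unit == "scan":
        by_scan = nodes.groupby(["scan_id", nodes["metastatic"].astype(bool)])["localized"].mean()
        recall_groups = {
            "non-mets": by_scan.xs(False, level=1).to_numpy(),
            "mets": by_scan.xs(True, level=1).to_numpy(),
        }
    else:
        raise ValueError(f"unknown recall_test_unit {recall_test_unit!r}")
    results["recall_by_status"] = compare_groups_kw(recall_groups, alpha)
    results["sensitivity_by_status"] = compare_groups_kw(
        {
            "non-mets": nodes.loc[~status, "sensitivity"].to_numpy(),
            "mets": nodes.loc[status, "sensitivity"].to_numpy(),
        },
        alpha,
    )
    bin_groups = {
        b: nodes.loc[nodes["sad_bin"] == b, "localized"].astype(float).to_numpy()
        for b in sad_bin_labels(bin_edges)
    }
    bin_groups = {b: v for b, v in bin_groups.items() if len(v) >= 2}
    if len(bin_groups) >= 2:
        results["recall_by_sad_bin"] = compare_groups_kw(bin_groups, alpha)
    if len(bin_groups) >= 3:
        results["recall_by_sad_bin_posthoc"] = posthoc_pairwise(
            bin_groups, alpha, correction=posthoc_correction
        )
    if len(nodes) >= 3:
        results["sensitivity_normality"] = normality_screen(
            nodes["sensitivity"].to_numpy(), alpha
        )
        try:
            results["sad_sensitivity_all"] = sad_sensitivity_correlation(nodes, None, alpha)
            results["sad_sensitivity_gt10"] = sad_sensitivity_correlation(nodes, 10.0, alpha)
        except ValueError as exc:
            logger.warning("correlation skipped: %s", exc)

    return CohortReport(
        strata=table,
        cohort_recall_macro=macro,
        cohort_recall_micro=micro,
        fps_per_scan_mean=float(np.sum(fps) / n_scans),
        fp_mean_sad_mm=float(np.mean(fp_sads)) if fp_sads else None,
        fp_large_per_scan=float(sum(1 for s in fp_sads if s >= 10.0) / n_scans),
        n_scans=n_scans,
        n_nodes=int(len(nodes)),
        mean_dice=float(np.mean(dices)) if dices else None,
        mean_avg_hausdorff_mm=float(np.mean(ahds)) if ahds else None,
        stats=results,
    )
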