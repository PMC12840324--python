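"""End-to-end scan and cohort evaluation.

Stage order per scan (fixed):

1. connected-component instance extraction on both masks;
2. removal of predicted components with SAD < ``min_pred_sad_mm``;
3. GT-centric localization matching and FP classification;
4. detection metrics (recall, precision, F1, FPs and their sizes);
5. global Dice and average Hausdorff distance on the FP/FN-filtered masks;
6. cohort aggregation, size/status stratification and group statistics.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io as nio
from .cohort_stats import CohortReport, aggregate_cohort
from .core import EvalConfig, LabelVolume, MatchReport
from .matching import match_scan, scan_detection_metrics
from .morphometry import assign_sad_bin, extract_instances, filter_small_predictions
from .seg_metrics import average_hausdorff, filtered_masks, global_dice

logger = logging.getLogger(__name__)

__all__ = ["ScanEvaluation", "evaluate_scan", "evaluate_cohort", "evaluate_directory"]


@dataclass
class ScanEvaluation:
    """Everything the pipeline derives from one GT/prediction pair."""

    scan_id: str
    metrics: dict
    match: MatchReport
    gt_nodes: pd.DataFrame  # node_id, sad_mm, sad_bin, metastatic, sensitivity, localized
    pred_nodes: pd.DataFrame  # pred_id, sad_mm, gt_overlap_fraction, is_fp
    removed_pred_ids: list[int]


def evaluate_scan(
    gt: LabelVolume,
    pred: LabelVolume,
    config: EvalConfig | None = None,
    metastatic: Mapping[int, bool] | None = None,
    scan_id: str = "scan",
) -> ScanEvaluation:
    """Evaluate one prediction mask against its ground truth."""
    config = config or EvalConfig()
    gt.require_same_grid(pred)
    gt_inst, gt_nodes = extract_instances(gt, config.connectivity)
    pred_inst, pred_nodes = extract_instances(pred, config.connectivity)
    pred_inst, pred_nodes, removed = filter_small_predictions(
        pred_inst, pred_nodes, config.min_pred_sad_mm
    )
    match = match_scan(gt_inst, pred_inst, config.tau_localize, config.theta_fp)

    fp_sads = [
        node.sad_mm
        for node, pm in zip(pred_nodes, match.per_pred)
        if pm.is_fp
    ]
    metrics = scan_detection_metrics(match, fp_sads)

    gt_f, pred_f = filtered_masks(gt_inst, pred_inst, match)
    metrics["global_dice"] = global_dice(gt_f, pred_f)
    ahd = average_hausdorff(gt_f, pred_f, gt.spacing, config.hausdorff_variant)
    if ahd is None and (gt_f.any() or pred_f.any()):
        logger.warning("%s: empty filtered mask, average Hausdorff undefined", scan_id)
    metrics["avg_hausdorff_mm"] = ahd

    meta = metastatic or {}
    gt_table = pd.DataFrame(
        {
            "scan_id": scan_id,
            "node_id": [n.id for n in gt_nodes],
            "sad_mm": [n.sad_mm for n in gt_nodes],
            "sad_bin": [assign_sad_bin(n.sad_mm, config.sad_bin_edges) for n in gt_nodes],
            "metastatic": [bool(meta.get(n.id, False)) for n in gt_nodes],
            "sensitivity": [m.sensitivity for m in match.per_gt],
            "localized": [m.localized for m in match.per_gt],
        }
    )
    pred_table = pd.DataFrame(
        {
            "scan_id": scan_id,
            "pred_id": [n.id for n in pred_nodes],
            "sad_mm": [n.sad_mm for n in pred_nodes],
            "gt_overlap_fraction": [m.gt_overlap_fraction for m in match.per_pred],
            "is_fp": [m.is_fp for m in match.per_pred],
        }
    )
    return ScanEvaluation(
        scan_id=scan_id,
        metrics=metrics,
        match=match,
        gt_nodes=gt_table,
        pred_nodes=pred_table,
        removed_pred_ids=removed,
    )


def evaluate_cohort(
    pairs: Iterable[tuple[str, LabelVolume, LabelVolume, Mapping[int, bool] | None]],
    config: EvalConfig | None = None,
) -> tuple[CohortReport, dict[str, ScanEvaluation]]:
    """Evaluate an iterable of (scan_id, gt, pred, metastatic-map) tuples."""
    config = config or EvalConfig()
    evaluations: dict[str, ScanEvaluation] = {}
    for scan_id, gt, pred, meta in pairs:
        evaluations[scan_id] = evaluate_scan(gt, pred, config, meta, scan_id)
    if not evaluations:
        raise ValueError("empty cohort")
    nodes = pd.concat(
        [ev.gt_nodes for ev in evaluations.values()], ignore_index=True
    )
    report = aggregate_cohort(
        {sid: ev.metrics for sid, ev in evaluations.items()},
        nodes,
        bin_edges=config.sad_bin_edges,
        alpha=config.alpha,
        recall_test_unit=config.recall_test_unit,
        posthoc_correction=config.posthoc_correction,
    )
    return report, evaluations


def _paired_files(gt_dir: Path, pred_dir: Path) -> list[tuple[str, Path, Path]]:
    def stem(p: Path) -> str:
        name = p.name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return p.stem

    gts = {stem(p): p for p in sorted(gt_dir.iterdir()) if p.name.endswith((".nii", ".nii.gz"))}
    preds = {stem(p): p for p in sorted(pred_dir.iterdir()) if p.name.endswith((".nii", ".nii.gz"))}
    missing = sorted(set(gts) - set(preds))
    if missing:
        raise FileNotFoundError(f"no prediction for scan(s): {missing}")
    extra = sorted(set(preds) - set(gts))
    if extra:
        raise FileNotFoundError(f"prediction without ground truth: {extra}")
    return [(sid, gts[sid], preds[sid]) for sid in sorted(gts)]


def evaluate_directory(
    gt_dir: str | os.PathLike,
    pred_dir: str | os.PathLike,
    metadata_csv: str | os.PathLike | None = None,
    config: EvalConfig | None = None,
) -> tuple[CohortReport, dict[str, ScanEvaluation]]:
    """Evaluate a cohort laid out as paired NIfTI directories.

    Scans are paired by file stem; every ground-truth scan must have a
    prediction and vice versa.  ``metadata_csv`` carries the per-node
    metastatic flags (``scan_id, node_id, metastatic``); absent nodes
    default to non-metastatic with a warning.
    """
    config = config or EvalConfig()
    pairs = _paired_files(Path(gt_dir), Path(pred_dir))

    def load_pairs():
        meta_map = None
        if metadata_csv is not None:
            raw = pd.read_csv(metadata_csv, dtype={"scan_id": str})
            if raw.duplicated(subset=["scan_id", "node_id"]).any():
                raise ValueError(f"{metadata_csv}: duplicate (scan_id, node_id) rows")
            meta_map = {
                sid: dict(zip(grp["node_id"].astype(int), grp["metastatic"].astype(bool)))
                for sid, grp in raw.groupby("scan_id")
            }
        for sid, gt_path, pred_path in pairs:
            gt = nio.load_label_volume(gt_path, "binary")
            pred = nio.load_label_volume(pred_path, "binary")
            meta = meta_map.get(sid, {}) if meta_map is not None else None
            yield sid, gt, pred, meta

    return evaluate_cohort(load_pairs(), config)
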