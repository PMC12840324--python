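"""Report rendering and on-disk layout for simulation and evaluation runs.

Everything is written as plain CSV/JSON; undefined cells (e.g. the mean
sensitivity of an empty stratum, or an average Hausdorff distance with an
empty filtered mask) are emitted as JSON ``null`` / empty CSV cells, never
as zeros.  The full configuration is echoed beside every report so each
threshold in the output is traceable.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as nio
from .cohort_stats import CohortReport
from .core import EvalConfig
from .pipeline import ScanEvaluation
from .synthetic import CohortConfig, DegradationConfig, iter_cohort

__all__ = [
    "write_simulated_cohort",
    "write_evaluation",
    "render_report",
]


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def write_simulated_cohort(
    cfg: CohortConfig,
    dcfg: Optional[DegradationConfig],
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Write a synthetic cohort: gt/pred NIfTI pairs plus metadata CSV.

    Layout: ``gt/<scan>.nii.gz``, ``pred/<scan>.nii.gz`` (when a
    degradation config is given), ``metadata.csv`` with per-instance rows
    ``scan_id, node_id, metastatic, necrotic, sad_mm``, and the generating
    configs echoed as JSON.  Returns the pooled metadata table.
    """
    out = Path(out_dir)
    (out / "gt").mkdir(parents=True, exist_ok=True)
    if dcfg is not None:
        (out / "pred").mkdir(exist_ok=True)
    rows = []
    for phantom, pred in iter_cohort(cfg, dcfg):
        nio.save_label_volume(phantom.gt, out / "gt" / f"{phantom.scan_id}.nii.gz")
        if pred is not None:
            nio.save_label_volume(pred, out / "pred" / f"{phantom.scan_id}.nii.gz")
        meta = phantom.nodes[["node_id", "metastatic", "necrotic", "sad_mm"]].copy()
        meta.insert(0, "scan_id", phantom.scan_id)
        meta["metastatic"] = meta["metastatic"].astype(int)
        meta["necrotic"] = meta["necrotic"].astype(int)
        rows.append(meta)
    metadata = pd.concat(rows, ignore_index=True)
    metadata.to_csv(out / "metadata.csv", index=False)
    _dump_json(
        {
            "cohort": cfg.to_dict(),
            "degradation": dcfg.to_dict() if dcfg else None,
        },
        out / "simulation_config.json",
    )
    return metadata


def write_evaluation(
    report: CohortReport,
    evaluations: Mapping[str, ScanEvaluation],
    config: EvalConfig,
    out_dir: str | os.PathLike,
) -> None:
    """Write per-scan metrics, node/prediction tables and the cohort report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_json(
        {sid: ev.metrics for sid, ev in evaluations.items()},
        out / "scan_metrics.json",
    )
    nodes = pd.concat([ev.gt_nodes for ev in evaluations.values()], ignore_index=True)
    nodes.to_csv(out / "nodes.csv", index=False)
    preds = pd.concat([ev.pred_nodes for ev in evaluations.values()], ignore_index=True)
    preds.to_csv(out / "predictions.csv", index=False)
    payload = report.to_dict()
    payload["config"] = config.to_dict()
    _dump_json(payload, out / "cohort_report.json")
    render_report(out, out)


def render_report(results_dir: str | os.PathLike, out_dir: str | os.PathLike) -> None:
    """Render tables from an evaluation directory.

    Produces ``stratified_table.csv`` (counts / recall / sensitivity by
    SAD stratum and nodal status, with an ``All`` column) and
    ``sad_sensitivity_scatter.csv`` with one (sad_mm, sensitivity,
    metastatic) triple per ground-truth node.
    """
    results = Path(results_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes_path = results / "nodes.csv"
    report_path = results / "cohort_report.json"
    if not nodes_path.exists() or not report_path.exists():
        raise FileNotFoundError(f"evaluation outputs missing in {results}")
    payload = json.loads(report_path.read_text())

    strata = payload["strata"]
    columns = list(next(iter(strata.values())).keys())
    rows = []
    for key, vals in strata.items():
        measure, status = key.split("|")
        rows.append(
            {"measure": measure, "status": status}
            | {c: ("" if vals[c] is None else vals[c]) for c in columns}
        )
    pd.DataFrame(rows).to_csv(out / "stratified_table.csv", index=False)

    nodes = pd.read_csv(nodes_path)
    nodes[["sad_mm", "sensitivity", "metastatic"]].to_csv(
        out / "sad_sensitivity_scatter.csv", index=False
    )
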