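"""GT-centric localization matching and FP classification.

A ground-truth node's *sensitivity* is the fraction of its voxels covered
by the predicted foreground; the node counts as localized when that
fraction is at least ``tau_localize`` (default 0.4, boundary inclusive).
Symmetrically, a predicted component is a false positive when less than
``theta_fp`` of its voxels lie on ground-truth tissue.

No one-to-one assignment is performed: when confluent ("bulky") disease
merges several ground-truth nodes into overlapping predictions, a single
predicted component can legitimately localize all of them, which is why an
IoU/bijective matching scheme is avoided here.
"""

from __future__ import annotations

import numpy as np

from .core import GtMatch, LabelVolume, MatchReport, PredMatch

__all__ = [
    "node_sensitivity",
    "localize_nodes",
    "classify_predictions",
    "match_scan",
    "scan_detection_metrics",
    "harmonic_f1",
]


def node_sensitivity(gt_instance: np.ndarray, pred_foreground: np.ndarray) -> float:
    """|GT ∩ Pred| / |GT| by voxel count for one GT instance mask."""
    if gt_instance.shape != pred_foreground.shape:
        raise ValueError("grid shape mismatch between GT instance and prediction")
    gt = gt_instance.astype(bool)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("empty GT instance has no sensitivity")
    covered = int(np.count_nonzero(gt & pred_foreground.astype(bool)))
    return covered / n_gt


def localize_nodes(
    gt_inst: LabelVolume, pred_foreground: np.ndarray, tau: float = 0.4
) -> list[GtMatch]:
    """Per-GT-instance sensitivity and localized flag (sensitivity >= tau)."""
    if gt_inst.kind != "instance":
        raise ValueError("localize_nodes expects an instance volume")
    pred = pred_foreground.astype(bool)
    labels = gt_inst.voxels
    n_labels = int(labels.max(initial=0))
    out: list[GtMatch] = []
    if n_labels == 0:
        return out
    flat = labels.ravel()
    totals = np.bincount(flat, minlength=n_labels + 1)
    covered = np.bincount(flat[pred.ravel()], minlength=n_labels + 1)
    for gt_id in range(1, n_labels + 1):
        sens = covered[gt_id] / totals[gt_id]
        out.append(GtMatch(gt_id=gt_id, sensitivity=float(sens), localized=bool(sens >= tau)))
    return out


def classify_predictions(
    pred_inst: LabelVolume, gt_foreground: np.ndarray, theta_fp: float = 0.4
) -> list[PredMatch]:
    """Per-prediction GT-overlap fraction and FP flag (fraction < theta_fp)."""
    if pred_inst.kind != "instance":
        raise ValueError("classify_predictions expects an instance volume")
    gt = gt_foreground.astype(bool)
    labels = pred_inst.voxels
    n_labels = int(labels.max(initial=0))
    out: list[PredMatch] = []
    if n_labels == 0:
        return out
    flat = labels.ravel()
    totals = np.bincount(flat, minlength=n_labels + 1)
    on_gt = np.bincount(flat[gt.ravel()], minlength=n_labels + 1)
    for pid in range(1, n_labels + 1):
        frac = on_gt[pid] / totals[pid]
        out.append(PredMatch(pred_id=pid, gt_overlap_fraction=float(frac), is_fp=bool(frac < theta_fp)))
    return out


def match_scan(
    gt_inst: LabelVolume,
    pred_inst: LabelVolume,
    tau_localize: float = 0.4,
    theta_fp: float = 0.4,
) -> MatchReport:
    """Full match report for one scan from GT and (filtered) prediction instances."""
    gt_inst.require_same_grid(pred_inst)
    return MatchReport(
        per_gt=localize_nodes(gt_inst, pred_inst.foreground(), tau_localize),
        per_pred=classify_predictions(pred_inst, gt_inst.foreground(), theta_fp),
        tau_localize=tau_localize,
        theta_fp=theta_fp,
    )


def harmonic_f1(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def scan_detection_metrics(
    match: MatchReport, fp_sads_mm: list[float] | None = None
) -> dict:
    """Recall / precision / F1 / FP count for one scan.

    * ``recall = localized / n_gt`` (``None`` when the scan has no GT nodes);
    * ``precision = (n_pred - n_fp) / n_pred``; with no predictions it is
      1.0 for an empty-GT scan and undefined (``None``) otherwise;
    * ``f1`` is the harmonic mean, ``None`` when either input is undefined.
    """
    n_gt, n_pred, n_fp = match.n_gt, match.n_pred, match.n_fp
    recall = match.n_localized / n_gt if n_gt > 0 else None
    if n_pred > 0:
        precision = (n_pred - n_fp) / n_pred
    else:
        precision = 1.0 if n_gt == 0 else None
    if recall is None or precision is None:
        f1 = None
    else:
        f1 = harmonic_f1(recall, precision)
    return {
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "fps": n_fp,
        "fp_sads_mm": list(fp_sads_mm or []),
        "n_gt": n_gt,
        "n_pred": n_pred,
    }
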