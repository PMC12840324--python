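"""Reference head-and-neck cohort summary used to calibrate the simulator.

These constants describe the published size/status structure of a 125-scan
contrast-CT cohort of head-and-neck-cancer patients with fully annotated
cervical lymph nodes, together with the detection performance of a generic
node-segmentation model on it.  The synthetic cohort generator's defaults
are derived from them, and the bookkeeping helpers reproduce the cohort's
self-contained arithmetic (node counts, pooled recalls, F1).

Size strata are by short-axis diameter (SAD): <5, 5–10, 10–15, >15 mm.
"""

from __future__ import annotations

import numpy as np

from .matching import harmonic_f1

__all__ = [
    "N_SCANS",
    "SAD_BIN_LABELS",
    "NODE_COUNTS",
    "BIN_RECALLS",
    "BIN_SENSITIVITIES",
    "SAD_SUMMARY",
    "FP_PER_SCAN",
    "FP_MEAN_SAD_MM",
    "FP_LARGE_PER_SCAN",
    "MACRO_RECALL",
    "PRECISION",
    "net_annotation_count",
    "nodes_per_scan",
    "pooled_recall",
    "localized_count",
]

N_SCANS = 125

# Annotation bookkeeping: nodes proposed by the support model, nodes the
# annotating radiologist rejected (too small or spurious), nodes added.
PROPOSED_NODES = 3798
REJECTED_NODES = 868
ADDED_NODES = 726

SAD_BIN_LABELS = ("<5", "5–10", "10–15", ">15")

# Ground-truth node counts per SAD stratum and nodal status.
NODE_COUNTS = {
    "all": (1906, 1474, 159, 117),
    "non-mets": (1869, 1228, 12, 3),
    "mets": (37, 246, 147, 114),
}

# Localization recall per stratum (fraction of nodes with sensitivity >= 0.4).
BIN_RECALLS = {
    "all": (0.72, 0.79, 0.67, 0.36),
    "non-mets": (0.71, 0.80, 0.67, 0.0),
    "mets": (0.89, 0.74, 0.67, 0.37),
}

# Mean per-node sensitivity per stratum; None where the stratum is too
# small to report (3 non-metastatic nodes > 15 mm).
BIN_SENSITIVITIES = {
    "all": (0.88, 0.89, 0.80, 0.67),
    "non-mets": (0.88, 0.89, 0.81, None),
    "mets": (0.94, 0.90, 0.80, 0.67),
}

# SAD distribution summary per status: (mean_mm, max_mm).
SAD_SUMMARY = {"non-mets": (5.0, 23.3), "mets": (11.3, 57.9)}

METASTATIC_LOCALIZED = 354  # of the 544 metastatic nodes

# Cohort-level detection figures.
MACRO_RECALL = 0.70  # per-scan average
PRECISION = 0.73
FP_PER_SCAN = 6.5
FP_MEAN_SAD_MM = 5.3
FP_LARGE_PER_SCAN = 0.3  # false positives with SAD >= 10 mm


def net_annotation_count(
    proposed: int = PROPOSED_NODES,
    rejected: int = REJECTED_NODES,
    added: int = ADDED_NODES,
) -> int:
    """Final ground-truth node count: proposed − rejected + added."""
    return proposed - rejected + added


def nodes_per_scan(total_nodes: int | None = None, n_scans: int = N_SCANS) -> float:
    """Average annotated nodes per scan."""
    if total_nodes is None:
        total_nodes = net_annotation_count()
    return total_nodes / n_scans


def pooled_recall(counts, recalls) -> float:
    """Node-count-weighted (micro) recall pooled over strata.

    Strata with an undefined recall (``None``) must have zero count.
    """
    counts = np.asarray(counts, dtype=float)
    recalls = np.asarray([0.0 if r is None else r for r in recalls], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no nodes to pool")
    return float((counts * recalls).sum() / total)


def localized_count(n_localized: int, n_total: int) -> float:
    """Recall from a localized/total node count pair."""
    if n_total <= 0:
        raise ValueError("total node count must be positive")
    return n_localized / n_total


def f1_score(recall: float = MACRO_RECALL, precision: float = PRECISION) -> float:
    """Cohort F1 from recall and precision."""
    return harmonic_f1(recall, precision)
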