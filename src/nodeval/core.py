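"""Domain types and evaluation configuration.

Conventions used throughout the package:

* Voxel grids are 3D integer arrays with axes ordered ``(x, y, z)``; axis 2
  is the axial (slice) axis.  The short-axis diameter is measured in the
  axial ``(x, y)`` plane, as in RECIST 1.1.
* Voxel indices are 0-based.  Physical coordinates are voxel-center based:
  ``position_mm = index * spacing``.
* Spacing is anisotropic and carried everywhere in mm; masks are never
  resampled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "LabelVolume",
    "NodeInstance",
    "GtMatch",
    "PredMatch",
    "MatchReport",
    "ScanMetrics",
    "StatResult",
    "EvalConfig",
]

VolumeKind = Literal["binary", "instance"]


@dataclass(frozen=True)
class LabelVolume:
    """A 3D label grid with physical voxel spacing.

    Parameters
    ----------
    voxels:
        Integer array of shape ``(nx, ny, nz)``; axis 2 is axial.
    spacing:
        ``(sx, sy, sz)`` voxel dimensions in mm, all strictly positive.
    kind:
        ``"binary"`` (values in {0, 1}) or ``"instance"`` (consecutive
        positive labels ``1..K`` plus background 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    kind: VolumeKind = "binary"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {vox.shape}")
        if not np.issubdtype(vox.dtype, np.integer):
            if np.issubdtype(vox.dtype, np.floating) and np.all(vox == np.round(vox)):
                vox = vox.astype(np.int32)
            else:
                raise ValueError("voxels must hold integer labels")
        if vox.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.kind == "binary":
            if vox.max(initial=0) > 1:
                raise ValueError("binary volume contains values outside {0, 1}")
        elif self.kind == "instance":
            labels = np.unique(vox)
            labels = labels[labels > 0]
            if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
                raise ValueError(
                    f"instance labels must be consecutive 1..K, got {labels.tolist()}"
                )
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def foreground(self) -> np.ndarray:
        """Boolean foreground mask (any positive label)."""
        return self.voxels > 0

    def same_grid(self, other: "LabelVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, atol=atol
        )

    def require_same_grid(self, other: "LabelVolume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )


@dataclass
class NodeInstance:
    """One connected node component and its morphometry."""

    id: int
    voxel_count: int
    volume_mm3: float
    sad_mm: float
    centroid_mm: tuple[float, float, float]
    metastatic: Optional[bool] = None
    necrotic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("instance id must be a positive label")
        if self.voxel_count < 1:
            raise ValueError("instance must contain at least one voxel")
        if self.volume_mm3 <= 0 or self.sad_mm <= 0:
            raise ValueError("volume and SAD must be positive")


@dataclass(frozen=True)
class GtMatch:
    """Localization outcome for one ground-truth instance."""

    gt_id: int
    sensitivity: float
    localized: bool


@dataclass(frozen=True)
class PredMatch:
    """False-positive classification for one predicted instance."""

    pred_id: int
    gt_overlap_fraction: float
    is_fp: bool


@dataclass
class MatchReport:
    """Per-scan matching result: GT-centric localization plus FP flags.

    Matching is deliberately not one-to-one: a single merged prediction
    component covering several touching ground-truth nodes can localize
    all of them, which is the behaviour required for bulky disease.
    """

    per_gt: list[GtMatch]
    per_pred: list[PredMatch]
    tau_localize: float = 0.4
    theta_fp: float = 0.4

    def __post_init__(self) -> None:
        gt_ids = [m.gt_id for m in self.per_gt]
        pred_ids = [m.pred_id for m in self.per_pred]
        if len(set(gt_ids)) != len(gt_ids):
            raise ValueError("duplicate gt_id in match report")
        if len(set(pred_ids)) != len(pred_ids):
            raise ValueError("duplicate pred_id in match report")
        for m in self.per_gt:
            if m.localized != (m.sensitivity >= self.tau_localize):
                raise ValueError(
                    f"gt {m.gt_id}: localized flag inconsistent with "
                    f"sensitivity {m.sensitivity} at tau {self.tau_localize}"
                )

    @property
    def n_gt(self) -> int:
        return len(self.per_gt)

    @property
    def n_pred(self) -> int:
        return len(self.per_pred)

    @property
    def n_localized(self) -> int:
        return sum(m.localized for m in self.per_gt)

    @property
    def n_fp(self) -> int:
        return sum(m.is_fp for m in self.per_pred)


@dataclass
class ScanMetrics:
    """Detection and segmentation summary for one scan.

    ``precision`` is ``None`` when there are no predictions but there are
    ground-truth nodes (undefined rather than zero); ``avg_hausdorff_mm``
    is ``None`` when either filtered mask is empty.
    """

    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    fps: int
    fp_sads_mm: list[float]
    global_dice: float
    avg_hausdorff_mm: Optional[float]
    n_gt: int
    n_pred: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fp_sads_mm"] = [float(s) for s in self.fp_sads_mm]
        return d


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    alpha: float = 0.01
    n_per_group: tuple[int, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["significant"] = self.significant
        return d


@dataclass
class EvalConfig:
    """All evaluation thresholds in one place.

    Defaults follow the evaluation protocol the package implements:
    predicted components with SAD < 4.5 mm are discarded as too small, a
    ground-truth node counts as localized when the predicted foreground
    covers >= 40% of its voxels, and a predicted component counts as a
    false positive when < 40% of its voxels lie on ground-truth tissue.
    """

    min_pred_sad_mm: float = 4.5
    tau_localize: float = 0.4
    theta_fp: float = 0.4
    sad_bin_edges: tuple[float, ...] = (5.0, 10.0, 15.0)
    alpha: float = 0.01
    connectivity: int = 26
    hausdorff_variant: str = "symmetric_average"  # or "directed_gt", "directed_pred"
    sad_method: str = "perpendicular"  # or "min_feret"
    recall_test_unit: str = "node"  # or "scan"
    posthoc_correction: Optional[str] = None  # or "holm"

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0.0 <= self.tau_localize <= 1.0:
            raise ValueError("tau_localize must lie in [0, 1]")
        if not 0.0 <= self.theta_fp <= 1.0:
            raise ValueError("theta_fp must lie in [0, 1]")
        if self.min_pred_sad_mm < 0:
            raise ValueError("min_pred_sad_mm must be non-negative")
        edges = tuple(float(e) for e in self.sad_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("sad_bin_edges must be strictly increasing")
        self.sad_bin_edges = edges

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "sad_bin_edges" in d:
            d["sad_bin_edges"] = tuple(d["sad_bin_edges"])
        return cls(**d)
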