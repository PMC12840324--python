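"""Synthetic phantom cohorts with the reference cohort's size structure.

The generator stands in for a private CT mask cohort: each scan is a 3D
grid in which lymph nodes are placed as randomly oriented digital
ellipsoids whose short-axis diameters follow truncated log-normal
distributions calibrated per nodal status (non-metastatic mean 5.0 mm,
max 23.3 mm; metastatic mean 11.3 mm, max 57.9 mm), with touching-node
clusters and central necrotic cores in large metastatic nodes.

A paired degradation model turns the ground truth into a plausible
"model prediction": per-node misses with size-stratum-specific
probabilities, one-voxel in-plane boundary erosion/dilation, necrotic-core
drop-out, and disjoint false-positive blobs at a Poisson rate per scan.
Miss events are sampled per ground-truth instance *before* boundary
degradation, so realized per-stratum recall is binomial with known
probability — the property the calibration checks rely on.

All randomness flows from a single cohort seed through per-scan spawned
generators, so every phantom is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from . import calibration
from .core import LabelVolume
from .morphometry import extract_instances, sad_bin_labels

__all__ = [
    "CohortConfig",
    "DegradationConfig",
    "ScanPhantom",
    "sample_gt_scan",
    "degrade_to_prediction",
    "expected_metrics",
    "iter_cohort",
]

@lru_cache(maxsize=32)
def _fit_truncated_lognormal(
    bin_fractions: tuple[float, ...],
    bin_edges: tuple[float, ...],
    min_mm: float,
    max_mm: float,
) -> tuple[float, float]:
    """(mu, sigma) of a [min, max]-truncated log-normal fitted to a size
    histogram (least squares over the stratum fractions).

    The reference cohort prints per-status node counts per SAD stratum,
    which pins both location and dispersion; the resulting truncated means
    reproduce the printed per-status mean SADs to within ~2%.
    """
    fracs = np.asarray(bin_fractions, dtype=float)
    fracs = fracs / fracs.sum()
    lo, hi = np.log(min_mm), np.log(max_mm)

    def trunc_cdf(x, mu, sigma):
        denom = stats.norm.cdf((hi - mu) / sigma) - stats.norm.cdf((lo - mu) / sigma)
        return (
            stats.norm.cdf((np.log(x) - mu) / sigma)
            - stats.norm.cdf((lo - mu) / sigma)
        ) / denom

    def objective(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        c = [trunc_cdf(np.clip(e, min_mm, max_mm), mu, sigma) for e in bin_edges]
        model = np.diff(np.concatenate([[0.0], c, [1.0]]))
        return float(np.sum((model - fracs) ** 2))

    res = optimize.minimize(
        objective,
        x0=[np.log(5.0), np.log(0.5)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    if not res.success or res.fun > 0.01:
        raise RuntimeError(f"log-normal calibration failed for {bin_fractions}")
    return float(res.x[0]), float(np.exp(res.x[1]))


_FP_SMALL_SIGMA = 0.35


@lru_cache(maxsize=32)
def _solve_fp_small_mu(
    mean_mm: float,
    min_mm: float,
    large_fraction: float,
    large_mm: float = 10.0,
    max_mm: float = 20.0,
) -> float:
    """Location of the small-FP size component.

    False-positive sizes are a two-component mixture: with probability
    ``large_fraction`` a log-uniform draw on [``large_mm``, ``max_mm``]
    (the rare clearly-large false positive), otherwise a log-normal
    truncated to [``min_mm``, ``large_mm``) — the typical just-above-the-
    size-filter blob.  A single log-normal cannot put the overall mean
    only ~0.8 mm above the filter floor while still reserving the reported
    large-FP fraction, so the tail is modelled explicitly.  The small
    component's location is solved so the mixture mean equals ``mean_mm``
    at fixed log-scale spread ``_FP_SMALL_SIGMA``.
    """
    mean_large = (max_mm - large_mm) / np.log(max_mm / large_mm)
    target_small = (mean_mm - large_fraction * mean_large) / (1.0 - large_fraction)
    if not min_mm < target_small < large_mm:
        raise ValueError(
            f"FP mean {mean_mm} mm incompatible with floor {min_mm} mm "
            f"and large fraction {large_fraction}"
        )
    lo, hi = np.log(min_mm), np.log(large_mm)
    s = _FP_SMALL_SIGMA

    def trunc_mean(mu):
        denom = stats.norm.cdf((hi - mu) / s) - stats.norm.cdf((lo - mu) / s)
        if denom < 1e-14:
            return min_mm if mu < lo else large_mm
        num = stats.norm.cdf((hi - mu - s * s) / s) - stats.norm.cdf((lo - mu - s * s) / s)
        return np.exp(mu + s * s / 2) * num / denom

    return float(optimize.brentq(lambda mu: trunc_mean(mu) - target_small, -20.0, hi + 5.0))


def _sample_truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, size=None
):
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=size)
    return dist.ppf(u)


@dataclass(frozen=True)
class CohortConfig:
    """Phantom cohort parameters, defaulting to the reference cohort.

    ``sad_distribution`` selects how node sizes are drawn: ``"calibrated"``
    uses the status-specific truncated log-normals; ``"stratified"`` draws
    the size stratum uniformly and the SAD uniformly within it, which
    populates every stratum evenly — the sampling used for parameter
    recovery, where per-stratum statistical power matters more than
    realistic size frequencies.
    """

    n_scans: int = calibration.N_SCANS
    nodes_per_scan_mean: float = 29.2
    metastatic_fraction: float = 544 / 3656
    sad_nonmet_max_mm: float = calibration.SAD_SUMMARY["non-mets"][1]
    sad_met_max_mm: float = calibration.SAD_SUMMARY["mets"][1]
    sad_nonmet_bin_counts: tuple[float, ...] = calibration.NODE_COUNTS["non-mets"]
    sad_met_bin_counts: tuple[float, ...] = calibration.NODE_COUNTS["mets"]
    sad_calibration_edges: tuple[float, ...] = (5.0, 10.0, 15.0)
    min_sad_mm: float = 3.0
    sad_distribution: str = "calibrated"  # or "stratified"
    stratified_ranges: tuple[tuple[float, float], ...] = (
        (3.5, 5.0),
        (5.0, 10.0),
        (10.0, 15.0),
        (15.0, 25.0),
    )
    cluster_probability: float = 0.05
    necrosis_sad_threshold_mm: float = 15.0
    necrosis_volume_fraction: float = 0.25
    grid_shape: tuple[int, int, int] = (160, 160, 80)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if not 0 <= self.metastatic_fraction <= 1:
            raise ValueError("metastatic_fraction must lie in [0, 1]")
        if not 0 <= self.cluster_probability <= 1:
            raise ValueError("cluster_probability must lie in [0, 1]")
        if not 0 < self.necrosis_volume_fraction < 1:
            raise ValueError("necrosis_volume_fraction must lie in (0, 1)")
        if self.sad_distribution not in ("calibrated", "stratified"):
            raise ValueError(f"unknown sad_distribution {self.sad_distribution!r}")
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.grid_shape):
            raise ValueError("invalid grid")

    def sad_params(self, metastatic: bool) -> tuple[float, float, float, float]:
        """(mu, sigma, lo, hi) of the status's truncated log-normal."""
        counts, hi = (
            (self.sad_met_bin_counts, self.sad_met_max_mm)
            if metastatic
            else (self.sad_nonmet_bin_counts, self.sad_nonmet_max_mm)
        )
        mu, sigma = _fit_truncated_lognormal(
            tuple(counts), tuple(self.sad_calibration_edges), self.min_sad_mm, hi
        )
        return mu, sigma, self.min_sad_mm, hi

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stratified_ranges"] = [list(r) for r in self.stratified_ranges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in (
            "grid_shape",
            "spacing",
            "sad_nonmet_bin_counts",
            "sad_met_bin_counts",
            "sad_calibration_edges",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "stratified_ranges" in d:
            d["stratified_ranges"] = tuple(tuple(r) for r in d["stratified_ranges"])
        return cls(**d)


@dataclass(frozen=True)
class DegradationConfig:
    """Prediction degradation model, defaulting to the reference model's
    observed behaviour.

    ``miss_probabilities`` are per SAD stratum (complements of the
    reference per-stratum recalls).  Boundary errors are one-voxel
    in-plane operations; erosion is restricted to nodes with SAD >=
    ``erosion_min_sad_mm`` so that boundary noise alone never pushes a
    node's coverage below the localization threshold.
    """

    miss_probabilities: tuple[float, ...] = (0.28, 0.21, 0.33, 0.64)
    sad_bin_edges: tuple[float, ...] = (5.0, 10.0, 15.0)
    dilation_probability: float = 0.25
    erosion_probability: float = 0.25
    dilation_radius: int = 1
    erosion_radius: int = 1
    erosion_min_sad_mm: float = 10.0
    necrosis_dropout_probability: float = 0.8
    fp_rate: float = calibration.FP_PER_SCAN
    fp_sad_mean_mm: float = calibration.FP_MEAN_SAD_MM
    fp_min_sad_mm: float = 4.6
    fp_large_fraction: float = calibration.FP_LARGE_PER_SCAN / calibration.FP_PER_SCAN
    fp_max_sad_mm: float = 20.0

    def __post_init__(self) -> None:
        if len(self.miss_probabilities) != len(self.sad_bin_edges) + 1:
            raise ValueError("need one miss probability per SAD stratum")
        if any(not 0 <= p <= 1 for p in self.miss_probabilities):
            raise ValueError("miss probabilities must lie in [0, 1]")
        if self.dilation_radius < 1 or self.erosion_radius < 1:
            raise ValueError("boundary-operation radii must be >= 1 voxel")
        for p in (
            self.dilation_probability,
            self.erosion_probability,
            self.necrosis_dropout_probability,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dilation_probability + self.erosion_probability > 1:
            raise ValueError("dilation + erosion probability exceeds 1")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")

    def miss_probability(self, sad_mm: float) -> float:
        idx = int(np.searchsorted(np.asarray(self.sad_bin_edges), sad_mm, side="right"))
        return self.miss_probabilities[idx]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DegradationConfig":
        d = dict(d)
        for key in ("miss_probabilities", "sad_bin_edges"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ScanPhantom:
    """One generated scan: ground truth, instance labels, metadata."""

    scan_id: str
    gt: LabelVolume  # binary
    instances: LabelVolume  # consecutive labels
    nodes: pd.DataFrame  # per instance: node_id, sad_mm, metastatic, necrotic
    necrosis_core: np.ndarray  # boolean, subset of gt foreground


# ---------------------------------------------------------------- geometry


def _ellipsoid_submask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_vox: np.ndarray,
    semi_axes_mm: tuple[float, float, float],
    theta: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Rasterize an in-plane-rotated ellipsoid; returns (bbox slices, mask)."""
    sx, sy, sz = spacing
    a, b, c = semi_axes_mm
    r_in = max(a, b)
    ext = np.array([r_in / sx, r_in / sy, c / sz])
    lo = np.maximum(np.floor(center_vox - ext - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + ext + 1).astype(int) + 1, shape)
    slc = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    xs = (np.arange(lo[0], hi[0]) - center_vox[0]) * sx
    ys = (np.arange(lo[1], hi[1]) - center_vox[1]) * sy
    zs = (np.arange(lo[2], hi[2]) - center_vox[2]) * sz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u = gx * ct + gy * st
    v = -gx * st + gy * ct
    mask = (u / a) ** 2 + (v / b) ** 2 + (gz / c) ** 2 <= 1.0
    return slc, mask


def _calibrated_submask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_vox: np.ndarray,
    semi_axes_mm: tuple[float, float, float],
    theta: float,
    target_sad_mm: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray, tuple[float, float, float]]:
    """Rasterize an ellipsoid, nudging the short semi-axis until the
    *measured* SAD of the digital mask matches the target.

    Small digital ellipsoids measure below their nominal size (few voxel
    centers fall near the minor-axis tangents), so up to three corrective
    re-rasterizations are applied; the result is within about half an
    in-plane voxel of the target for all but degenerate sizes.
    """
    from .morphometry import compute_sad

    a, b, c = semi_axes_mm
    inplane = min(spacing[0], spacing[1])
    slc, mask = _ellipsoid_submask(shape, spacing, center_vox, (a, b, c), theta)
    for _ in range(3):
        coords = np.argwhere(mask)
        if coords.size == 0:
            break
        measured = compute_sad(coords, spacing)
        err = target_sad_mm - measured
        if abs(err) <= 0.5 * inplane:
            break
        b = max(b + err / 2.0, 0.3 * inplane)
        a = max(a, b * 1.01)
        slc, mask = _ellipsoid_submask(shape, spacing, center_vox, (a, b, c), theta)
    return slc, mask, (a, b, c)


def _node_semi_axes(
    rng: np.random.Generator, sad_mm: float, spacing: Sequence[float]
) -> tuple[float, float, float]:
    """Semi-axes (long, short, z) in mm for a node of target SAD."""
    inplane = min(spacing[0], spacing[1])
    b = max((sad_mm - inplane) / 2.0, 0.6 * inplane)
    a = b * rng.uniform(1.05, 1.6)
    c = max(b * rng.uniform(0.7, 1.3), 0.55 * spacing[2])
    return a, b, c


def _boxes_overlap(box_a, box_b) -> bool:
    return all(a_lo < b_hi and b_lo < a_hi for (a_lo, a_hi), (b_lo, b_hi) in zip(box_a, box_b))


# ---------------------------------------------------------------- sampling


def _sample_target_sad(
    rng: np.random.Generator, cfg: CohortConfig, metastatic: bool
) -> float:
    if cfg.sad_distribution == "stratified":
        lo, hi = cfg.stratified_ranges[rng.integers(len(cfg.stratified_ranges))]
        return float(rng.uniform(lo, hi))
    mu, sigma, lo, hi = cfg.sad_params(metastatic)
    return float(_sample_truncated_lognormal(rng, mu, sigma, lo, hi))


def sample_gt_scan(
    cfg: CohortConfig, scan_seed: int | np.random.SeedSequence, scan_id: str = "scan"
) -> ScanPhantom:
    """Generate one ground-truth phantom scan.

    Nodes are placed without contact (two background voxels of clearance)
    except for deliberate touching clusters; each node's measured SAD lies
    within about one in-plane voxel of its sampled target.  Metastatic
    nodes at or above the necrosis threshold receive a concentric necrotic
    core of the configured volume fraction (part of the ground truth — the
    core is node tissue).

    Raises ``RuntimeError`` when a node cannot be placed after many
    attempts (grid too small for the requested cohort).
    """
    rng = np.random.default_rng(scan_seed)
    shape = cfg.grid_shape
    spacing = cfg.spacing
    gt = np.zeros(shape, dtype=np.int8)
    core = np.zeros(shape, dtype=bool)
    inplane = min(spacing[0], spacing[1])

    n_nodes = max(1, int(rng.poisson(cfg.nodes_per_scan_mean)))
    placed_boxes: list[tuple[tuple[float, float], ...]] = []
    records = []  # (center_vox, semi_axes, theta, metastatic, necrotic)

    def try_place(sad_mm: float, near: Optional[tuple] = None):
        """Place one ellipsoid; ``near`` requests contact with that node."""
        axes = _node_semi_axes(rng, sad_mm, spacing)
        ext = np.array(
            [max(axes[0], axes[1]) / spacing[0], max(axes[0], axes[1]) / spacing[1], axes[2] / spacing[2]]
        )
        pad = 2.0
        bounds = [(e + pad + 1, s - e - pad - 1) for e, s in zip(ext, shape)]
        if any(hi <= lo for lo, hi in bounds):
            raise RuntimeError(
                f"could not place a {sad_mm:.1f} mm node in grid {shape}; "
                "increase grid_shape or reduce node sizes"
            )
        for _ in range(500):
            theta = rng.uniform(0, np.pi)
            if near is None:
                center = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            else:
                n_center, n_axes = near
                phi = rng.uniform(0, 2 * np.pi)
                # each ellipsoid contains the in-plane ball of its short
                # semi-axis, so this spacing guarantees overlap (touching)
                gap = 0.7 * (n_axes[1] + axes[1])
                center = n_center + np.array(
                    [gap * np.cos(phi) / spacing[0], gap * np.sin(phi) / spacing[1], 0.0]
                )
                if np.any(center < ext + 1) or np.any(center > np.array(shape) - ext - 1):
                    continue
            box = tuple(
                (c - e - pad, c + e + pad) for c, e in zip(center, ext)
            )
            others = placed_boxes if near is None else placed_boxes[:-1]
            if any(_boxes_overlap(box, other) for other in others):
                continue
            placed_boxes.append(box)
            return center, axes, theta
        raise RuntimeError(
            f"could not place a {sad_mm:.1f} mm node in grid {shape}; "
            "increase grid_shape or reduce nodes_per_scan_mean"
        )

    count = 0
    while count < n_nodes:
        metastatic = bool(rng.uniform() < cfg.metastatic_fraction)
        sad = _sample_target_sad(rng, cfg, metastatic)
        center, axes, theta = try_place(sad)
        necrotic = metastatic and sad >= cfg.necrosis_sad_threshold_mm
        records.append((center, axes, theta, sad, metastatic, necrotic))
        count += 1
        if count < n_nodes and rng.uniform() < cfg.cluster_probability:
            # touching companion of the same status (bulky disease)
            sad2 = _sample_target_sad(rng, cfg, metastatic)
            try:
                center2, axes2, theta2 = try_place(sad2, near=(center, axes))
            except RuntimeError:
                continue
            necrotic2 = metastatic and sad2 >= cfg.necrosis_sad_threshold_mm
            records.append((center2, axes2, theta2, sad2, metastatic, necrotic2))
            count += 1

    final_axes = []
    for center, axes, theta, sad, metastatic, necrotic in records:
        slc, mask, axes = _calibrated_submask(shape, spacing, center, axes, theta, sad)
        final_axes.append(axes)
        gt[slc][mask] = 1
        if necrotic:
            scale = cfg.necrosis_volume_fraction ** (1.0 / 3.0)
            cslc, cmask = _ellipsoid_submask(
                shape, spacing, center, tuple(x * scale for x in axes), theta
            )
            core[cslc][cmask] = True

    gt_vol = LabelVolume(voxels=gt.astype(np.int16), spacing=spacing, kind="binary")
    inst, instances = extract_instances(gt_vol, connectivity=26)

    # instance-level flags: an instance is metastatic/necrotic when any of
    # its generating nodes is (touching clusters share one instance)
    met_flags = {n.id: False for n in instances}
    nec_flags = {n.id: False for n in instances}
    for (center, _axes, theta, _sad, metastatic, necrotic), axes in zip(records, final_axes):
        label = int(inst.voxels[tuple(np.round(center).astype(int))])
        if label == 0:  # center rounded off the ellipsoid: look nearby
            slc, mask = _ellipsoid_submask(shape, spacing, center, axes, theta)
            labels_here = np.unique(inst.voxels[slc][mask])
            labels_here = labels_here[labels_here > 0]
            label = int(labels_here[0]) if labels_here.size else 0
        if label:
            met_flags[label] = met_flags[label] or metastatic
            nec_flags[label] = nec_flags[label] or necrotic

    nodes = pd.DataFrame(
        {
            "node_id": [n.id for n in instances],
            "voxel_count": [n.voxel_count for n in instances],
            "volume_mm3": [n.volume_mm3 for n in instances],
            "sad_mm": [n.sad_mm for n in instances],
            "metastatic": [met_flags[n.id] for n in instances],
            "necrotic": [nec_flags[n.id] for n in instances],
        }
    )
    return ScanPhantom(
        scan_id=scan_id, gt=gt_vol, instances=inst, nodes=nodes, necrosis_core=core
    )


# -------------------------------------------------------------- degradation

_INPLANE_CROSS = np.zeros((3, 3, 1), dtype=bool)
_INPLANE_CROSS[1, :, 0] = True
_INPLANE_CROSS[:, 1, 0] = True


def degrade_to_prediction(
    phantom: ScanPhantom,
    dcfg: DegradationConfig,
    seed: int | np.random.SeedSequence,
) -> LabelVolume:
    """Simulate the model's prediction mask for one phantom scan.

    Stage order: per-instance miss draw (probability by measured SAD
    stratum) → boundary erosion/dilation of surviving instances →
    necrotic-core drop-out → false-positive blobs placed clear of both the
    ground truth and the prediction so far.
    """
    rng = np.random.default_rng(seed)
    shape = phantom.gt.shape
    spacing = phantom.gt.spacing
    pred = np.zeros(shape, dtype=bool)
    objects = ndimage.find_objects(phantom.instances.voxels)

    for row in phantom.nodes.itertuples(index=False):
        if rng.uniform() < dcfg.miss_probability(row.sad_mm):
            continue
        slc = objects[row.node_id - 1]
        # halo so dilation has room
        halo = dcfg.dilation_radius
        slc = tuple(
            slice(max(s.start - halo, 0), min(s.stop + halo, dim))
            for s, dim in zip(slc, shape)
        )
        sub = phantom.instances.voxels[slc] == row.node_id
        u = rng.uniform()
        if u < dcfg.dilation_probability:
            sub = ndimage.binary_dilation(
                sub, structure=_INPLANE_CROSS, iterations=dcfg.dilation_radius
            )
        elif (
            u < dcfg.dilation_probability + dcfg.erosion_probability
            and row.sad_mm >= dcfg.erosion_min_sad_mm
        ):
            sub = ndimage.binary_erosion(
                sub,
                structure=_INPLANE_CROSS,
                iterations=dcfg.erosion_radius,
                border_value=0,
            )
        if row.necrotic and rng.uniform() < dcfg.necrosis_dropout_probability:
            sub = sub & ~phantom.necrosis_core[slc]
        pred[slc] |= sub

    if dcfg.fp_rate > 0:
        mu_small = _solve_fp_small_mu(
            dcfg.fp_sad_mean_mm,
            dcfg.fp_min_sad_mm,
            dcfg.fp_large_fraction,
            max_mm=dcfg.fp_max_sad_mm,
        )
        n_fp = int(rng.poisson(dcfg.fp_rate))
        occupied = phantom.gt.foreground()
        for _ in range(n_fp):
            if rng.uniform() < dcfg.fp_large_fraction:
                sad = float(
                    np.exp(rng.uniform(np.log(10.0), np.log(dcfg.fp_max_sad_mm)))
                )
            else:
                sad = float(
                    _sample_truncated_lognormal(
                        rng, mu_small, _FP_SMALL_SIGMA, dcfg.fp_min_sad_mm, 10.0
                    )
                )
            inplane = min(spacing[0], spacing[1])
            b = (sad - inplane) / 2.0
            axes = (b * rng.uniform(1.0, 1.3), b, max(b * rng.uniform(0.7, 1.2), 0.55 * spacing[2]))
            ext = np.array(
                [axes[0] / spacing[0], axes[0] / spacing[1], axes[2] / spacing[2]]
            )
            fp_bounds = [(e + 3, s - e - 3) for e, s in zip(ext, shape)]
            if any(hi <= lo for lo, hi in fp_bounds):
                continue  # blob larger than the grid allows: skip it
            for _attempt in range(200):
                center = np.array([rng.uniform(lo, hi) for lo, hi in fp_bounds])
                theta = rng.uniform(0, np.pi)
                slc, mask, _ = _calibrated_submask(
                    shape, spacing, center, axes, theta, sad
                )
                gslc = tuple(
                    slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                    for s, dim in zip(slc, shape)
                )
                region = np.zeros(tuple(g.stop - g.start for g in gslc), dtype=bool)
                inner = tuple(
                    slice(s.start - g.start, s.stop - g.start) for s, g in zip(slc, gslc)
                )
                region[inner] = mask
                grown = ndimage.binary_dilation(
                    region, structure=np.ones((3, 3, 3), dtype=bool)
                )
                if (grown & (occupied[gslc] | pred[gslc])).any():
                    continue
                pred[slc] |= mask
                break

    return LabelVolume(voxels=pred.astype(np.int16), spacing=spacing, kind="binary")


def expected_metrics(cfg: CohortConfig, dcfg: DegradationConfig) -> dict:
    """Closed-form expectations the degradation model is built to satisfy."""
    labels = sad_bin_labels(dcfg.sad_bin_edges)
    return {
        "recall_per_bin": {
            lab: 1.0 - p for lab, p in zip(labels, dcfg.miss_probabilities)
        },
        "fps_per_scan": dcfg.fp_rate,
    }


def iter_cohort(
    cfg: CohortConfig, dcfg: Optional[DegradationConfig] = None
) -> Iterator[tuple[ScanPhantom, Optional[LabelVolume]]]:
    """Yield (phantom, prediction) pairs for the whole cohort.

    Per-scan seeds are spawned deterministically from ``cfg.seed``; the
    prediction is ``None`` when no degradation config is given.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_scans)
    for i, child in enumerate(children):
        gt_seed, pred_seed = child.spawn(2)
        scan_id = f"scan{i:03d}"
        phantom = sample_gt_scan(cfg, gt_seed, scan_id=scan_id)
        pred = degrade_to_prediction(phantom, dcfg, pred_seed) if dcfg else None
        yield phantom, pred
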