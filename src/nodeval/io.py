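"""Mask and metadata I/O.

Volumes are stored as NIfTI (``.nii`` / ``.nii.gz``); the first two array
axes are the in-plane axes and the third is the axial (slice) axis, so the
header zooms map directly onto :class:`~nodeval.core.LabelVolume` spacing.
Loading never resamples, thresholds or otherwise alters voxel values.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LabelVolume, VolumeKind

logger = logging.getLogger(__name__)

__all__ = ["load_label_volume", "save_label_volume", "load_node_metadata"]


def load_label_volume(
    path: str | os.PathLike,
    expected_kind: VolumeKind = "binary",
    relabel: bool = False,
) -> LabelVolume:
    """Read a 3D NIfTI label volume.

    Parameters
    ----------
    path:
        NIfTI file with integer labels and strictly positive zooms.
    expected_kind:
        ``"binary"`` or ``"instance"``; the voxel values are validated
        against the corresponding contract.
    relabel:
        For instance volumes only: map non-consecutive positive labels onto
        ``1..K`` (preserving order) instead of rejecting them.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, non-3D image, non-positive spacing, or labels that
        violate ``expected_kind``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: non-integer label values")
        data = rounded
    data = data.astype(np.int32)
    if relabel and expected_kind == "instance":
        labels = np.unique(data)
        labels = labels[labels > 0]
        lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
        lut[labels] = np.arange(1, labels.size + 1, dtype=np.int32)
        data = lut[data]
    return LabelVolume(voxels=data, spacing=tuple(float(z) for z in zooms), kind=expected_kind)


def save_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a :class:`LabelVolume` as NIfTI; round-trips voxels exactly."""
    sx, sy, sz = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    dtype = np.int16 if vol.voxels.max(initial=0) < 2**15 else np.int32
    img = nib.Nifti1Image(vol.voxels.astype(dtype), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def load_node_metadata(
    path: str | os.PathLike,
    known_ids: Mapping[str, set[int]] | None = None,
) -> dict[tuple[str, int], bool]:
    """Read per-node metastatic flags from a CSV sidecar.

    The CSV must carry columns ``scan_id, node_id, metastatic`` with
    ``metastatic`` in {0, 1}.  When ``known_ids`` (scan -> set of instance
    labels present in the mask) is given, CSV rows for absent nodes are
    warned about and dropped, and mask instances absent from the CSV
    default to non-metastatic with a warning.

    Returns a mapping ``(scan_id, node_id) -> metastatic``.
    """
    df = pd.read_csv(path, dtype={"scan_id": str})
    required = {"scan_id", "node_id", "metastatic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["scan_id", "node_id"])
    if dup.any():
        rows = df.loc[dup, ["scan_id", "node_id"]].to_records(index=False).tolist()
        raise ValueError(f"{path}: duplicate (scan_id, node_id) rows: {rows[:5]}")
    out: dict[tuple[str, int], bool] = {}
    for row in df.itertuples(index=False):
        key = (str(row.scan_id), int(row.node_id))
        if known_ids is not None:
            ids = known_ids.get(key[0], set())
            if key[1] not in ids:
                logger.warning("metadata row %s not present in mask; ignored", key)
                continue
        out[key] = bool(int(row.metastatic))
    if known_ids is not None:
        for scan, ids in known_ids.items():
            for nid in sorted(ids):
                if (scan, nid) not in out:
                    logger.warning(
                        "node %s/%d missing from metadata; defaulting to non-metastatic",
                        scan,
                        nid,
                    )
                    out[(scan, nid)] = False
    return out
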