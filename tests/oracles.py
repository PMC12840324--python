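"""Brute-force reference implementations used only by the tests.

Everything here is written for transparency, not speed: breadth-first
flood fill for components, exhaustive point-pair projections for the
short-axis diameter, explicit neighbor loops for boundary extraction and
exhaustive pairwise distances for the average surface distance.  These
stay independent of the package code paths they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if 0 < abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by BFS flood fill."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = _OFFSETS[connectivity]
    current = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(n, mask.shape)):
                    if mask[n] and not labels[n]:
                        labels[n] = current
                        queue.append(n)
    return labels


def brute_sad(coords: np.ndarray, spacing) -> float:
    """Exhaustive short-axis diameter: per axial slice, try every voxel
    pair as the long axis and take the perpendicular projection extent of
    every voxel center; plus one in-plane voxel; maximum over slices."""
    coords = np.asarray(coords)
    sx, sy, _ = (float(s) for s in spacing)
    inplane = min(sx, sy)
    best = 0.0
    for z in np.unique(coords[:, 2]):
        pts = coords[coords[:, 2] == z, :2].astype(float) * (sx, sy)
        n = len(pts)
        if n == 1:
            continue
        best_d2, pair = -1.0, None
        for i in range(n):
            for j in range(i + 1, n):
                d2 = float(np.sum((pts[i] - pts[j]) ** 2))
                if d2 > best_d2:
                    best_d2, pair = d2, (i, j)
        if best_d2 <= 0:
            continue
        u = pts[pair[1]] - pts[pair[0]]
        u = u / np.linalg.norm(u)
        v = np.array([-u[1], u[0]])
        proj = pts @ v
        best = max(best, float(proj.max() - proj.min()) + inplane)
    return max(best, inplane)


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def brute_sensitivity(gt: np.ndarray, pred: np.ndarray) -> float:
    gt, pred = gt.astype(bool), pred.astype(bool)
    return np.count_nonzero(gt & pred) / np.count_nonzero(gt)


def brute_boundary(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with at least one background 6-neighbor."""
    mask = mask.astype(bool)
    out = []
    for x, y, z in map(tuple, np.argwhere(mask)):
        for dx, dy, dz in _OFFSETS[6]:
            n = (x + dx, y + dy, z + dz)
            if not all(0 <= c < s for c, s in zip(n, mask.shape)) or not mask[n]:
                out.append((x, y, z))
                break
    return out


def brute_avg_hausdorff(a: np.ndarray, b: np.ndarray, spacing) -> float | None:
    """Symmetric average surface distance via exhaustive pairwise search."""
    pa = np.asarray(brute_boundary(a), dtype=float)
    pb = np.asarray(brute_boundary(b), dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        return None
    s = np.asarray(spacing, dtype=float)
    pa, pb = pa * s, pb * s

    def directed(src, dst):
        mins = []
        for p in src:
            mins.append(min(float(np.linalg.norm(p - q)) for q in dst))
        return float(np.mean(mins))

    return 0.5 * (directed(pa, pb) + directed(pb, pa))


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Textbook Kruskal–Wallis H on tie-free data (hand-rolled ranking)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
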