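"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity by exhaustive search or per-item
enumeration, sharing no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def rotation_search_hd(vertices: np.ndarray, step_deg: float = 0.01) -> float:
    """Longer side of the minimum-area bounding rectangle by exhaustive
    rotation of the axis-aligned bounding box over [0, 180) degrees."""
    pts = np.asarray(vertices, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    cos, sin = np.cos(angles), np.sin(angles)
    u = pts @ np.vstack([cos, sin])  # (n_pts, n_angles) projections on axis 1
    v = pts @ np.vstack([-sin, cos])  # projections on the orthogonal axis
    width = u.max(axis=0) - u.min(axis=0)
    height = v.max(axis=0) - v.min(axis=0)
    areas = width * height
    k = int(np.argmin(areas))
    return float(max(width[k], height[k]))


def feret_extremes(vertices: np.ndarray, step_deg: float = 0.05) -> tuple[float, float]:
    """(min, max) Feret diameter by brute-force rotation of the caliper."""
    pts = np.asarray(vertices, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    proj = pts @ np.vstack([np.cos(angles), np.sin(angles)])
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), float(widths.max())


def pair_iou(a, b) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    return inter / ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)


def brute_force_nms(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> list[int]:
    """O(n^2) greedy suppression: indices of surviving boxes, score-descending."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    kept: list[int] = []
    for i in order:
        if all(pair_iou(boxes[i], boxes[j]) <= threshold for j in kept):
            kept.append(int(i))
    return kept


def lexicographic_ids(positions: np.ndarray, ridges: np.ndarray) -> np.ndarray:
    """Plant IDs by explicit sort of (ridge asc, y desc, x asc) tuples."""
    records = sorted(
        range(len(ridges)),
        key=lambda i: (ridges[i], -positions[i, 1], positions[i, 0]),
    )
    ids = np.empty(len(ridges), dtype=int)
    for rank, idx in enumerate(records, start=1):
        ids[idx] = rank
    return ids


def per_item_income(hds_cm, classes, sellable) -> float:
    """Income by per-head enumeration: ``classes`` is a list of
    (lower, upper, price) half-open intervals, ``sellable`` a (min, max)
    inclusive envelope."""
    total = 0.0
    for hd in hds_cm:
        if hd < sellable[0] or hd > sellable[1]:
            continue
        for lo, hi, price in classes:
            if lo <= hd < hi or (hd == sellable[1] and lo <= hd <= hi):
                total += price
                break
    return total
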