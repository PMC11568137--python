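"""Vessel junction detection on skeletonized masks."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .transform import PointSet

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _merge_close(points: np.ndarray, radius: float) -> np.ndarray:
    """Union-find clustering of points closer than ``radius``; centroids."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return np.array([points[idx].mean(axis=0) for idx in clusters.values()])


def detect_junctions(vessel_mask: np.ndarray, frame: str = "device-px",
                     merge_radius_px: float = 5.0) -> PointSet:
    """Junction points of a binary vessel mask.

    The mask is skeletonized; skeleton pixels with >= 3 skeleton
    neighbours are junction candidates, and candidates closer than the
    merge radius are collapsed to their centroid. Coordinates are
    returned as (x, y) = (column, row).
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        return PointSet(np.empty((0, 2)), frame=frame)
    skel = skeletonize(mask)
    neighbors = convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                         mode="constant")
    junc = skel & (neighbors >= 3)
    rows, cols = np.nonzero(junc)
    if len(rows) == 0:
        return PointSet(np.empty((0, 2)), frame=frame)
    pts = np.column_stack([cols, rows]).astype(float)
    merged = _merge_close(pts, merge_radius_px)
    return PointSet(merged, frame=frame)
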