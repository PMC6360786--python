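"""Shared nearest-neighbor helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def mean_nn_distance(points: np.ndarray) -> float:
    """Mean distance of each point to its single nearest neighbor."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points for a neighbor distance")
    d, _ = cKDTree(points).query(points, k=2)
    return float(d[:, 1].mean())


def knn_mean_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean distance to the k nearest neighbors (self excluded)."""
    points = np.asarray(points, dtype=float)
    if len(points) <= k:
        raise ValueError(f"need more than k={k} points")
    d, _ = cKDTree(points).query(points, k=k + 1)
    return d[:, 1:].mean(axis=1)
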