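"""Point-cloud container.

Coordinates are meters in a local frame.  Per-point labels use small
integer codes so they round-trip through LAS classification bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNLABELED = 0
GROUND = 1
VEGETATION = 2
OUTLIER = 3

_LABEL_NAMES = {UNLABELED: "unlabeled", GROUND: "ground",
                VEGETATION: "vegetation", OUTLIER: "outlier"}


@dataclass
class PointCloud:
    """Unordered 3D points with an optional per-point label.

    Parameters
    ----------
    xyz : (N, 3) float array
        Point coordinates in meters.
    labels : (N,) int array, optional
        One of ``UNLABELED``, ``GROUND``, ``VEGETATION``, ``OUTLIER``.
    """

    xyz: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.labels is None:
            self.labels = np.full(len(self.xyz), UNLABELED, dtype=np.int8)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int8).reshape(-1)
            if len(self.labels) != len(self.xyz):
                raise ValueError("labels length must match point count")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cloud; raises on empty clouds."""
        if len(self) == 0:
            raise ValueError("empty cloud has no extent")
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz[mask], self.labels[mask])

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz.copy(), labels)

    def label_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {_LABEL_NAMES.get(int(v), str(int(v))): int(c)
                for v, c in zip(vals, counts)}
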