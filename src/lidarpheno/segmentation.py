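"""Grid-based individual-plant segmentation.

Every vegetation point of a normalized plot cloud is assigned to exactly
one planting-grid cell by half-open binning (right/top edge exclusive);
the cell's points are treated as one individual.  Leaves overhanging a
neighboring cell are deliberately not reassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cloud import GROUND, OUTLIER, PointCloud
from .errors import GridCoverageError


@dataclass
class PlantCloud:
    """Points of one grid cell attributed to one individual."""

    plant_id: str
    variety_id: int          # column index
    row: int
    cell_bounds: tuple[float, float, float, float]
    xyz: np.ndarray
    stage: str | None = None
    missing: bool = field(init=False)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.missing = len(self.xyz) == 0

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


def segment_grid(cloud: PointCloud, origin: tuple[float, float] | None,
                 n_cols: int, n_rows: int, col_spacing: float = 0.50,
                 row_spacing: float = 0.30, stage: str | None = None,
                 on_orphans: str = "error") -> list[PlantCloud]:
    """Partition the vegetation points of `cloud` into per-cell plants.

    Cells are half-open: a point exactly on a shared edge goes to the
    higher-index cell.  Vegetation points outside the grid raise
    :class:`GridCoverageError` (with the orphan count) by default, or
    are silently discarded with ``on_orphans="drop"``.
    """
    if on_orphans not in ("error", "drop"):
        raise ValueError("on_orphans must be 'error' or 'drop'")
    exclude = (cloud.labels == GROUND) | (cloud.labels == OUTLIER)
    pts = cloud.xyz[~exclude]
    if origin is None:
        if len(pts) == 0:
            origin = (0.0, 0.0)
        else:
            origin = (math.floor(pts[:, 0].min() / col_spacing) * col_spacing,
                      math.floor(pts[:, 1].min() / row_spacing) * row_spacing)
    x0, y0 = origin
    ci = np.floor((pts[:, 0] - x0) / col_spacing).astype(np.int64)
    ri = np.floor((pts[:, 1] - y0) / row_spacing).astype(np.int64)
    orphan = (ci < 0) | (ci >= n_cols) | (ri < 0) | (ri >= n_rows)
    if orphan.any():
        if on_orphans == "error":
            raise GridCoverageError(int(orphan.sum()))
        pts, ci, ri = pts[~orphan], ci[~orphan], ri[~orphan]

    order = np.lexsort((ri, ci))
    key = ci[order] * n_rows + ri[order]
    plants = []
    # locate each cell's contiguous run in the sorted point list
    starts = np.searchsorted(key, np.arange(n_cols * n_rows), side="left")
    ends = np.searchsorted(key, np.arange(n_cols * n_rows), side="right")
    sorted_pts = pts[order]
    for col in range(n_cols):
        for row in range(n_rows):
            k = col * n_rows + row
            cell_pts = sorted_pts[starts[k]:ends[k]]
            plants.append(PlantCloud(
                plant_id=f"c{col}_r{row}", variety_id=col, row=row,
                cell_bounds=(x0 + col * col_spacing, y0 + row * row_spacing,
                             x0 + (col + 1) * col_spacing,
                             y0 + (row + 1) * row_spacing),
                xyz=cell_pts, stage=stage))
    return plants
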