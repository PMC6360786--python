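"""Plot-level preprocessing chain.

Order matters: statistical outlier removal, ground/vegetation
classification by simplified progressive TIN densification, DTM
interpolation by ordinary kriging, height normalization against the DTM,
and random thinning to a target average point distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .cloud import GROUND, VEGETATION, PointCloud
from .errors import LidarPhenoError
from .kriging import fit_variogram, krige
from .neighbors import knn_mean_distances, mean_nn_distance


@dataclass(frozen=True)
class OutlierParams:
    """Statistical outlier rule: drop points whose mean distance to their
    k nearest neighbors exceeds avg + n_sigma * std of those means."""

    k_neighbors: int = 10
    n_sigma: float = 3.0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_sigma <= 0:
            raise ValueError("n_sigma must be > 0")


def remove_outliers(cloud: PointCloud,
                    params: OutlierParams = OutlierParams()
                    ) -> tuple[PointCloud, int]:
    """Filter isolated points; returns (filtered cloud, removed count)."""
    n = len(cloud)
    if n <= params.k_neighbors:
        raise LidarPhenoError(
            f"cloud has {n} points; need more than k={params.k_neighbors}")
    mean_d = knn_mean_distances(cloud.xyz, params.k_neighbors)
    avg, std = mean_d.mean(), mean_d.std()
    if std <= 1e-12 * max(avg, 1.0):  # degenerate spread: keep everything
        return cloud.select(np.ones(n, dtype=bool)), 0
    keep = mean_d <= avg + params.n_sigma * std
    return cloud.select(keep), int((~keep).sum())


def classify_ground(cloud: PointCloud, cell: float = 1.0,
                    max_angle: float = 30.0, max_dist: float = 0.05,
                    iterations: int = 3) -> PointCloud:
    """Label every point ground or vegetation.

    Simplified progressive TIN densification: per-cell minima seed a
    Delaunay triangulation; points close to their containing triangle
    (vertical distance <= max_dist, max point-to-vertex angle <=
    max_angle) are accepted as ground and the TIN is redensified.
    """
    n = len(cloud)
    if n == 0:
        raise LidarPhenoError("cannot classify an empty cloud")
    xyz = cloud.xyz
    xmin, ymin = xyz[:, :2].min(axis=0)
    ix = np.floor((xyz[:, 0] - xmin) / cell).astype(np.int64)
    iy = np.floor((xyz[:, 1] - ymin) / cell).astype(np.int64)
    key = ix * (iy.max() + 1) + iy
    order = np.lexsort((xyz[:, 2], key))
    first = np.ones(n, dtype=bool)
    first[1:] = key[order][1:] != key[order][:-1]
    seed_idx = order[first]
    if len(seed_idx) < 3:
        raise LidarPhenoError(
            f"only {len(seed_idx)} seed cells; cannot triangulate")

    is_ground = np.zeros(n, dtype=bool)
    is_ground[seed_idx] = True
    tan_max = math.tan(math.radians(max_angle))

    for _ in range(max(1, iterations)):
        nodes = _thin_lowest(xyz[is_ground], cell / 4.0)
        nodes = np.vstack([nodes, _boundary_nodes(xyz, nodes)])
        try:
            tri = Delaunay(nodes[:, :2])
        except Exception as exc:  # degenerate seed geometry
            raise LidarPhenoError(f"seed triangulation failed: {exc}") from exc
        cand = np.flatnonzero(~is_ground)
        if len(cand) == 0:
            break
        simplex = tri.find_simplex(xyz[cand, :2])
        inside = simplex >= 0
        cand, simplex = cand[inside], simplex[inside]
        verts = nodes[tri.simplices[simplex]]          # (m, 3, 3)
        dz = xyz[cand, 2] - _plane_z(verts, xyz[cand, :2])
        hdist = np.linalg.norm(
            verts[:, :, :2] - xyz[cand, None, :2], axis=2)  # (m, 3)
        with np.errstate(divide="ignore", invalid="ignore"):
            tangents = np.abs(dz)[:, None] / hdist
        tangents = np.where(hdist < 1e-9,
                            np.where(np.abs(dz)[:, None] < 1e-9, 0.0, np.inf),
                            tangents)
        accept = (np.abs(dz) <= max_dist) & (tangents.max(axis=1) <= tan_max)
        if not accept.any():
            break
        is_ground[cand[accept]] = True

    labels = np.where(is_ground, GROUND, VEGETATION).astype(np.int8)
    return cloud.with_labels(labels)


def _thin_lowest(points: np.ndarray, cell: float) -> np.ndarray:
    """Keep the lowest point per xy cell (keeps the TIN small)."""
    if len(points) == 0:
        return points
    ij = np.floor(points[:, :2] / cell).astype(np.int64)
    key = (ij[:, 0] - ij[:, 0].min()) * (np.ptp(ij[:, 1]) + 1) \
        + (ij[:, 1] - ij[:, 1].min())
    order = np.lexsort((points[:, 2], key))
    first = np.ones(len(points), dtype=bool)
    first[1:] = key[order][1:] != key[order][:-1]
    return points[order[first]]


def _boundary_nodes(xyz: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Virtual support nodes on the bounding box so the TIN spans the
    whole cloud; each takes the elevation of the nearest real node."""
    xmin, ymin = xyz[:, :2].min(axis=0) - 1e-6
    xmax, ymax = xyz[:, :2].max(axis=0) + 1e-6
    xs = np.linspace(xmin, xmax, 4)
    ys = np.linspace(ymin, ymax, 4)
    border = [(x, ymin) for x in xs] + [(x, ymax) for x in xs] + \
             [(xmin, y) for y in ys[1:-1]] + [(xmax, y) for y in ys[1:-1]]
    border = np.array(border)
    from scipy.spatial import cKDTree
    _, nearest = cKDTree(nodes[:, :2]).query(border)
    return np.column_stack([border, nodes[nearest, 2]])


def _plane_z(verts: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """z of each triangle's plane at xy.  verts: (m,3,3), xy: (m,2)."""
    p0, p1, p2 = verts[:, 0], verts[:, 1], verts[:, 2]
    n = np.cross(p1 - p0, p2 - p0)
    nz = np.where(np.abs(n[:, 2]) < 1e-12, 1e-12, n[:, 2])
    d = -(n * p0).sum(axis=1)
    return -(n[:, 0] * xy[:, 0] + n[:, 1] * xy[:, 1] + d) / nz


@dataclass
class TerrainModel:
    """Raster DTM; grid[i, j] is the elevation at the center of cell
    (i, j), cells are half-open [x0 + j*res, x0 + (j+1)*res)."""

    origin: tuple[float, float]
    resolution: float
    grid: np.ndarray  # (nrows, ncols)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.grid = np.asarray(self.grid, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.resolution
        ys = y0 + (np.arange(nrows) + 0.5) * self.resolution
        return xs, ys

    def interpolate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear elevation lookup; errors on points outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        x0, y0 = self.origin
        nrows, ncols = self.grid.shape
        res = self.resolution
        out = (x < x0 - 1e-9) | (x > x0 + ncols * res + 1e-9) | \
              (y < y0 - 1e-9) | (y > y0 + nrows * res + 1e-9)
        if out.any():
            bad_x = (float(x[out].min()), float(x[out].max()))
            bad_y = (float(y[out].min()), float(y[out].max()))
            raise LidarPhenoError(
                f"{int(out.sum())} point(s) outside DTM extent: "
                f"x in {bad_x}, y in {bad_y}; DTM covers "
                f"x [{x0}, {x0 + ncols * res}], y [{y0}, {y0 + nrows * res}]")
        xs, ys = self.cell_centers()
        # clamp into the center lattice; edge strips extrapolate flat
        gx = np.clip((x - xs[0]) / res, 0, ncols - 1 if ncols > 1 else 0)
        gy = np.clip((y - ys[0]) / res, 0, nrows - 1 if nrows > 1 else 0)
        j0 = np.clip(np.floor(gx).astype(int), 0, max(ncols - 2, 0))
        i0 = np.clip(np.floor(gy).astype(int), 0, max(nrows - 2, 0))
        tx = np.clip(gx - j0, 0.0, 1.0)
        ty = np.clip(gy - i0, 0.0, 1.0)
        j1 = np.minimum(j0 + 1, ncols - 1)
        i1 = np.minimum(i0 + 1, nrows - 1)
        g = self.grid
        return ((1 - ty) * ((1 - tx) * g[i0, j0] + tx * g[i0, j1])
                + ty * ((1 - tx) * g[i1, j0] + tx * g[i1, j1]))


def build_dtm(cloud: PointCloud, resolution: float = 0.05,
              origin: tuple[float, float] | None = None,
              bounds: tuple[float, float, float, float] | None = None,
              max_data: int = 4000) -> TerrainModel:
    """Ordinary-kriging DTM from the ground-labeled points of `cloud`
    (or all points if unlabeled)."""
    if resolution <= 0:
        raise LidarPhenoError("resolution must be > 0")
    mask = cloud.labels == GROUND
    pts = cloud.xyz[mask] if mask.any() else cloud.xyz
    if len(pts) < 10:
        raise LidarPhenoError(f"need >= 10 ground points, got {len(pts)}")
    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 1].min(),
                  pts[:, 0].max(), pts[:, 1].max())
    x0, y0 = origin if origin is not None else (bounds[0], bounds[1])
    ncols = max(1, math.ceil((bounds[2] - x0) / resolution - 1e-9))
    nrows = max(1, math.ceil((bounds[3] - y0) / resolution - 1e-9))

    data = pts
    if len(data) > max_data:
        data = _thin_lowest(data, max(resolution,
                                      math.sqrt((bounds[2] - x0) *
                                                (bounds[3] - y0) / max_data)))
    vario = fit_variogram(data[:, :2], data[:, 2])
    xs = x0 + (np.arange(ncols) + 0.5) * resolution
    ys = y0 + (np.arange(nrows) + 0.5) * resolution
    qx, qy = np.meshgrid(xs, ys)
    query = np.column_stack([qx.ravel(), qy.ravel()])
    z = krige(data[:, :2], data[:, 2], query, vario)
    return TerrainModel((x0, y0), resolution, z.reshape(nrows, ncols))


def normalize_heights(cloud: PointCloud, dtm: TerrainModel) -> PointCloud:
    """Subtract the interpolated ground elevation from every point."""
    z_ground = dtm.interpolate(cloud.x, cloud.y)
    xyz = cloud.xyz.copy()
    xyz[:, 2] -= z_ground
    return PointCloud(xyz, cloud.labels.copy())


def resample_to_point_distance(cloud: PointCloud, target: float, seed: int,
                               tolerance: float = 0.05,
                               max_iter: int = 25) -> PointCloud:
    """Randomly thin the cloud until its mean nearest-neighbor distance is
    within `tolerance` of `target`.  Output point count never exceeds the
    input's; a fixed seed gives identical output."""
    current = mean_nn_distance(cloud.xyz)
    if target < current * (1 - 1e-9):
        raise LidarPhenoError(
            f"target {target:.6f} m is below the current average point "
            f"distance {current:.6f} m; thinning cannot densify")
    if abs(target - current) / target <= 1e-9:
        return cloud
    rng = np.random.default_rng(seed)
    n = len(cloud)
    frac = min(1.0, (current / target) ** 2)
    best = None
    for _ in range(max_iter):
        m = max(2, int(round(frac * n)))
        idx = rng.choice(n, size=m, replace=False)
        achieved = mean_nn_distance(cloud.xyz[idx])
        err = abs(achieved - target) / target
        if best is None or err < best[0]:
            best = (err, idx)
        if err <= tolerance:
            break
        frac = min(1.0, frac * (achieved / target) ** 2)
    return cloud.select(np.sort(best[1]))
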