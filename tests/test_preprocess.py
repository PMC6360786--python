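import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lidarpheno.cloud import GROUND, VEGETATION, PointCloud
from lidarpheno.errors import LidarPhenoError
from lidarpheno.kriging import krige
from lidarpheno.neighbors import mean_nn_distance
from lidarpheno.preprocess import (OutlierParams, TerrainModel, build_dtm,
                                   classify_ground, normalize_heights,
                                   remove_outliers,
                                   resample_to_point_distance)


def _grid_cloud(n=10, spacing=1.0, z=0.0):
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    pts = np.column_stack([xx.ravel(), yy.ravel(),
                           np.full(n * n, float(z))])
    return PointCloud(pts)


def _brute_force_outliers(xyz, k, n_sigma):
    """O(N^2) recomputation of the statistical outlier rule."""
    d = cdist(xyz, xyz)
    np.fill_diagonal(d, np.inf)
    mean_d = np.sort(d, axis=1)[:, :k].mean(axis=1)
    thr = mean_d.mean() + n_sigma * mean_d.std()
    return set(np.flatnonzero(mean_d > thr))


class TestRemoveOutliers:
    def test_isolated_point_removed(self):
        cloud = _grid_cloud(10, 1.0)
        far = np.vstack([cloud.xyz, [[20.0, 20.0, 5.0]]])
        out, removed = remove_outliers(PointCloud(far),
                                       OutlierParams(8, 3.0))
        assert removed == 1
        assert not np.any(np.all(out.xyz == [20.0, 20.0, 5.0], axis=1))

    def test_degenerate_spread_nothing_removed(self):
        # perfectly symmetric configuration: every point has the same
        # mean neighbor distance, std collapses to 0, nothing removed
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta),
                                np.zeros(100)])
        for n_sigma in (0.5, 3.0, 10.0):
            out, removed = remove_outliers(PointCloud(ring),
                                           OutlierParams(4, n_sigma))
            assert removed == 0 and len(out) == len(ring)

    def test_matches_brute_force_oracle(self, rng):
        xyz = rng.normal(0, 1, (500, 3))
        planted = rng.uniform(8, 12, (10, 3))
        all_pts = np.vstack([xyz, planted])
        params = OutlierParams(10, 3.0)
        out, removed = remove_outliers(PointCloud(all_pts), params)
        expected = _brute_force_outliers(all_pts, 10, 3.0)
        kept = {tuple(p) for p in out.xyz}
        got = {i for i, p in enumerate(all_pts) if tuple(p) not in kept}
        assert got == expected
        assert removed == len(expected)

    def test_idempotent_when_spread_collapses(self):
        cloud = _grid_cloud(8, 0.5)
        once, _ = remove_outliers(cloud, OutlierParams(6, 3.0))
        twice, removed = remove_outliers(once, OutlierParams(6, 3.0))
        assert removed == 0
        assert np.array_equal(once.xyz, twice.xyz)

    def test_too_few_points_errors(self):
        with pytest.raises(LidarPhenoError):
            remove_outliers(PointCloud(np.zeros((5, 3))),
                            OutlierParams(10, 3.0))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            OutlierParams(0, 3.0)
        with pytest.raises(ValueError):
            OutlierParams(10, 0.0)


class TestClassifyGround:
    def test_flat_plane_all_ground(self, rng):
        xyz = np.column_stack([rng.uniform(0, 5, 2000),
                               rng.uniform(0, 5, 2000),
                               np.zeros(2000)])
        labeled = classify_ground(PointCloud(xyz))
        assert np.all(labeled.labels == GROUND)

    def test_clear_separation(self, rng):
        ground = np.column_stack([rng.uniform(0, 5, 3000),
                                  rng.uniform(0, 5, 3000),
                                  np.zeros(3000)])
        plant = np.column_stack([rng.uniform(2, 3, 500),
                                 rng.uniform(2, 3, 500),
                                 rng.uniform(0.3, 1.5, 500)])
        cloud = PointCloud(np.vstack([ground, plant]))
        labeled = classify_ground(cloud, max_dist=0.1)
        assert np.all(labeled.labels[3000:] == VEGETATION)

    def test_labels_partition_cloud(self, clean_scene):
        labeled = classify_ground(clean_scene.cloud)
        assert set(np.unique(labeled.labels)) <= {GROUND, VEGETATION}

    def test_synthetic_truth_accuracy(self, clean_scene):
        labeled = classify_ground(clean_scene.cloud)
        accuracy = (labeled.labels == clean_scene.true_labels).mean()
        assert accuracy >= 0.99

    def test_too_few_seed_cells(self):
        xyz = np.array([[0.0, 0.0, 0.0], [0.1, 0.1, 0.0]])
        with pytest.raises(LidarPhenoError):
            classify_ground(PointCloud(xyz), cell=10.0)


class TestBuildDtm:
    def test_constant_field(self, rng):
        xyz = np.column_stack([rng.uniform(0, 2, 50),
                               rng.uniform(0, 2, 50),
                               np.full(50, 2.0)])
        dtm = build_dtm(PointCloud(xyz), resolution=0.25)
        assert np.allclose(dtm.grid, 2.0, atol=1e-10)

    def test_plane_oracle(self):
        xs = np.arange(0, 10.01, 0.25)
        gx, gy = np.meshgrid(xs, xs)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        z = 0.01 * pts[:, 0] + 0.02 * pts[:, 1]
        xyz = np.column_stack([pts, z])
        dtm = build_dtm(PointCloud(xyz), resolution=0.5, max_data=10000)
        xs, ys = dtm.cell_centers()
        qx, qy = np.meshgrid(xs, ys)
        truth = 0.01 * qx + 0.02 * qy
        assert np.abs(dtm.grid - truth).max() < 1e-3

    def test_exact_at_colocated_data_point(self, rng):
        # a data point sitting exactly on a cell center is reproduced
        xs = np.linspace(0.05, 0.95, 10)
        xx, yy = np.meshgrid(xs, xs)
        z = np.sin(xx * 3) + yy
        xyz = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
        dtm = build_dtm(PointCloud(xyz), resolution=0.1, origin=(0.0, 0.0))
        assert np.abs(dtm.grid - z.reshape(10, 10)).max() < 1e-8

    def test_kriging_weights_sum_to_one(self, rng):
        pts = rng.uniform(0, 5, (60, 2))
        z = np.sin(pts[:, 0]) + pts[:, 1] ** 2 / 10
        q = rng.uniform(0.5, 4.5, (30, 2))
        _, w, _ = krige(pts, z, q, return_weights=True)
        assert np.abs(w.sum(axis=1) - 1).max() < 1e-10

    def test_too_few_ground_points(self):
        with pytest.raises(LidarPhenoError):
            build_dtm(PointCloud(np.random.rand(5, 3)))


class TestNormalizeHeights:
    def test_flat_dtm_subtraction(self):
        dtm = TerrainModel((0.0, 0.0), 1.0, np.full((3, 3), 1.0))
        cloud = PointCloud(np.array([[1.5, 1.5, 2.5]]))
        out = normalize_heights(cloud, dtm)
        assert out.z[0] == pytest.approx(1.5)

    def test_point_outside_dtm_errors(self):
        dtm = TerrainModel((0.0, 0.0), 1.0, np.zeros((2, 2)))
        cloud = PointCloud(np.array([[5.0, 5.0, 1.0]]))
        with pytest.raises(LidarPhenoError, match="outside DTM"):
            normalize_heights(cloud, dtm)

    def test_ground_self_normalizes_near_zero(self, clean_scene):
        labeled = classify_ground(clean_scene.cloud)
        dtm = build_dtm(labeled)
        norm = normalize_heights(labeled, dtm)
        ground_z = norm.z[norm.labels == GROUND]
        assert np.abs(np.median(ground_z)) < 0.01
        assert np.percentile(np.abs(ground_z), 95) < 0.03

    def test_plant_heights_recovered(self, clean_scene):
        from lidarpheno.phenotypes import plant_height
        from lidarpheno.segmentation import segment_grid
        labeled = classify_ground(clean_scene.cloud)
        dtm = build_dtm(labeled)
        norm = normalize_heights(labeled, dtm)
        plants = segment_grid(norm, (0.0, 0.0), 4, 3, on_orphans="drop")
        truth = {r.plant_id: r.true_height for r in clean_scene.records}
        errs = [abs(plant_height(p) - truth[p.plant_id])
                for p in plants if not p.missing]
        assert np.median(errs) < 0.02


class TestResample:
    def _grid(self, spacing=0.005, n=100):
        xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
        return PointCloud(np.column_stack(
            [xx.ravel(), yy.ravel(), np.zeros(n * n)]))

    def test_target_equal_current_unchanged(self):
        cloud = self._grid()
        current = mean_nn_distance(cloud.xyz)
        out = resample_to_point_distance(cloud, current, seed=0)
        assert np.array_equal(out.xyz, cloud.xyz)

    def test_target_below_density_errors(self):
        cloud = self._grid()
        with pytest.raises(LidarPhenoError):
            resample_to_point_distance(cloud, 0.001, seed=0)

    def test_achieves_target_within_tolerance(self):
        cloud = self._grid()
        out = resample_to_point_distance(cloud, 0.010, seed=1)
        achieved = mean_nn_distance(out.xyz)
        assert abs(achieved - 0.010) / 0.010 <= 0.05
        assert len(out) <= len(cloud)

    def test_density_scaling(self):
        # retained fraction scales as 1/target^2 in 2D-dominated clouds
        cloud = self._grid(n=120)
        f10 = len(resample_to_point_distance(cloud, 0.010, seed=2)) \
            / len(cloud)
        f20 = len(resample_to_point_distance(cloud, 0.020, seed=2)) \
            / len(cloud)
        assert f10 / f20 == pytest.approx(4.0, rel=0.25)

    def test_determinism(self):
        cloud = self._grid()
        a = resample_to_point_distance(cloud, 0.012, seed=7)
        b = resample_to_point_distance(cloud, 0.012, seed=7)
        assert np.array_equal(a.xyz, b.xyz)
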