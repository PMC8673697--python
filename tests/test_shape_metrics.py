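import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import endobench as eb
from endobench.shape_metrics import SRE_MAX


def sphere_samples(n=5000, seed=0, normalized=True):
    mesh = eb.make_sphere_phantom(10.0, subdivisions=4)
    cloud = eb.sample_mesh_to_pointcloud(mesh, n, seed=seed)
    return eb.normalize_model(cloud) if normalized else cloud


class TestNormalize:
    def test_longest_edge_becomes_one(self):
        cloud = eb.PointCloud(np.random.default_rng(0).random((100, 3)) * [7, 3, 1])
        out = eb.normalize_model(cloud)
        ext = out.points.max(axis=0) - out.points.min(axis=0)
        assert ext.max() == pytest.approx(1.0, abs=1e-12)

    def test_centered_at_origin(self):
        cloud = eb.PointCloud(np.random.default_rng(1).random((50, 3)) + 5.0)
        out = eb.normalize_model(cloud)
        center = (out.points.max(axis=0) + out.points.min(axis=0)) / 2
        np.testing.assert_allclose(center, 0.0, atol=1e-12)

    def test_idempotent(self):
        cloud = eb.PointCloud(np.random.default_rng(2).random((50, 3)) * 4)
        once = eb.normalize_model(cloud)
        twice = eb.normalize_model(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)

    def test_works_on_meshes(self):
        mesh = eb.make_sphere_phantom(10.0, subdivisions=2)
        out = eb.normalize_model(mesh)
        assert out.extents.max() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            eb.normalize_model(eb.PointCloud(np.zeros((5, 3))))


class TestIcp:
    def test_recovers_small_perturbation(self):
        """5 degrees + 0.02 offset on sphere samples comes back within
        1e-3 of the inverse perturbation."""
        gt = sphere_samples(5000, seed=3)
        R = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        t = np.array([0.02, 0.0, 0.0])
        rec = eb.PointCloud(gt.points @ R.T + t, normalized=True)
        T, registered = eb.icp_register(rec, gt, max_iter=100, tol=1e-12)
        np.testing.assert_allclose(T[:3, :3], R.T, atol=1e-3)
        np.testing.assert_allclose(T[:3, 3], -R.T @ t, atol=1e-3)
        assert eb.compute_sre(registered, gt) < 1e-3

    def test_identity_for_identical_clouds(self):
        gt = sphere_samples(2000, seed=4)
        T, registered = eb.icp_register(gt, gt)
        np.testing.assert_allclose(T, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(registered.points, gt.points, atol=1e-12)

    def test_rms_non_increasing(self):
        gt = sphere_samples(3000, seed=5)
        rng = np.random.default_rng(6)
        R = Rotation.from_euler("xyz", [8, -5, 3], degrees=True).as_matrix()
        rec = eb.PointCloud(
            gt.points @ R.T + rng.normal(scale=0.003, size=3), normalized=True
        )
        history: list[float] = []
        eb.icp_register(rec, gt, max_iter=50, tol=1e-12, history=history)
        assert len(history) >= 3
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_empty_cloud_rejected(self):
        gt = sphere_samples(100, seed=7)
        with pytest.raises(ValueError):
            eb.icp_register(eb.PointCloud(np.empty((0, 3))), gt)


class TestSre:
    def test_zero_for_identical(self):
        gt = sphere_samples(1000, seed=8)
        assert eb.compute_sre(gt, gt) == 0.0

    def test_hand_computed_example(self):
        rec = eb.PointCloud([[0, 0, 0], [1, 0, 0]])
        gt = eb.PointCloud([[0, 0, 0]])
        assert eb.compute_sre(rec, gt) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_opposite_corner_reaches_theoretical_maximum(self):
        """One point per cloud at opposite unit-cube corners: the RMS
        distance is the box diagonal sqrt(3) ~ 1.732."""
        gt = eb.PointCloud([[-0.5, -0.5, -0.5]])
        rec = eb.PointCloud([[0.5, 0.5, 0.5]])
        assert eb.compute_sre(rec, gt) == pytest.approx(SRE_MAX, abs=1e-12)
        assert round(SRE_MAX, 3) == 1.732

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_nearest_neighbour(self, seed):
        rng = np.random.default_rng(seed)
        rec = eb.PointCloud(rng.random((150, 3)))
        gt = eb.PointCloud(rng.random((200, 3)))
        d2 = ((rec.points[:, None, :] - gt.points[None, :, :]) ** 2).sum(-1)
        expected = float(np.sqrt(d2.min(axis=1).mean()))
        assert eb.compute_sre(rec, gt) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_rec_duplication(self):
        rng = np.random.default_rng(3)
        rec = eb.PointCloud(rng.random((100, 3)))
        gt = eb.PointCloud(rng.random((100, 3)))
        doubled = eb.PointCloud(np.vstack([rec.points] * 10))
        assert eb.compute_sre(doubled, gt) == pytest.approx(
            eb.compute_sre(rec, gt), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            eb.compute_sre(eb.PointCloud(np.empty((0, 3))), sphere_samples(10))


class TestVoxelize:
    def test_floor_binning(self):
        grid = eb.voxelize(eb.PointCloud([[0.05, 0.0, 0.13]]), edge=0.04)
        np.testing.assert_array_equal(grid.occupied, [[1, 0, 3]])

    def test_empty_cloud(self):
        assert len(eb.voxelize(eb.PointCloud(np.empty((0, 3))), 0.04)) == 0

    def test_duplicates_collapse(self):
        pts = np.array([[0.01, 0.01, 0.01], [0.02, 0.02, 0.02], [0.5, 0.5, 0.5]])
        grid = eb.voxelize(eb.PointCloud(pts), edge=0.04)
        assert len(grid) == 2

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_density_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 3))
        a = eb.voxelize(eb.PointCloud(pts), 0.1)
        b = eb.voxelize(eb.PointCloud(np.vstack([pts] * 10)), 0.1)
        np.testing.assert_array_equal(a.occupied, b.occupied)

    def test_bad_edge_rejected(self):
        with pytest.raises(ValueError):
            eb.voxelize(eb.PointCloud([[0, 0, 0]]), edge=0.0)


class TestSrc:
    def test_identical_clouds_give_100_percent(self):
        gt = sphere_samples(10_000, seed=9)
        assert eb.compute_src(gt, gt) == 100.0

    def test_partial_voxel_coverage(self):
        """gt occupies 10 voxels; rec covers 6 of them -> 60%."""
        edge = 0.04
        gt_pts = np.array([[i * edge + edge / 2, 0.01, 0.01] for i in range(10)])
        rec_pts = gt_pts[:6]
        src = eb.compute_src(
            eb.PointCloud(rec_pts), eb.PointCloud(gt_pts), edge=edge
        )
        assert src == pytest.approx(60.0, abs=1e-12)

    def test_far_outlier_only_gives_zero(self):
        gt = eb.PointCloud([[0.0, 0.0, 0.0]])
        rec = eb.PointCloud([[5.0, 5.0, 5.0]])
        assert eb.compute_src(rec, gt) == 0.0

    def test_adding_rec_points_never_decreases(self):
        rng = np.random.default_rng(10)
        gt = sphere_samples(3000, seed=11)
        subset = gt.points[rng.random(len(gt)) < 0.5]
        more = np.vstack([subset, gt.points[:500]])
        src_small = eb.compute_src(eb.PointCloud(subset), gt)
        src_big = eb.compute_src(eb.PointCloud(more), gt)
        assert src_big >= src_small

    def test_density_invariance(self):
        gt = sphere_samples(2000, seed=12)
        rec = eb.PointCloud(gt.points[:1000])
        dense = eb.PointCloud(np.vstack([rec.points] * 10))
        assert eb.compute_src(dense, gt) == eb.compute_src(rec, gt)

    def test_strict_literal_matches_default_at_defaults(self):
        gt = sphere_samples(2000, seed=13)
        rec = eb.PointCloud(gt.points[::2])
        assert eb.compute_src(rec, gt) == eb.compute_src(
            rec, gt, strict_literal=True
        )

    def test_capped_at_100_with_generous_threshold(self):
        gt = sphere_samples(1000, seed=14)
        rec = eb.PointCloud(np.vstack([gt.points, gt.points + 0.001]))
        assert eb.compute_src(rec, gt, threshold=0.5) <= 100.0

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            eb.compute_src(sphere_samples(10), eb.PointCloud(np.empty((0, 3))))


class TestEvaluateShapeStage:
    @pytest.fixture(scope="class")
    def gt_mesh(self):
        return eb.make_sphere_phantom(10.0, subdivisions=4)

    def test_perfect_reconstruction(self, gt_mesh):
        rec = eb.sample_mesh_to_pointcloud(gt_mesh, 10_000, seed=0)
        m = eb.evaluate_shape_stage(rec, gt_mesh, "pcl", n_samples=10_000, seed=0)
        assert m.sre == pytest.approx(0.0, abs=1e-9)
        assert m.src == 100.0
        assert m.stage == "pcl"

    def test_scale_invariance(self, gt_mesh):
        """Pre-scaling the reconstruction is erased by normalization."""
        rec = eb.sample_mesh_to_pointcloud(gt_mesh, 5000, seed=1)
        rng = np.random.default_rng(2)
        noisy = eb.PointCloud(rec.points + rng.normal(scale=0.02, size=rec.points.shape))
        scaled = eb.PointCloud(noisy.points * 37.5)
        m1 = eb.evaluate_shape_stage(noisy, gt_mesh, "pcl", n_samples=5000, seed=1)
        m2 = eb.evaluate_shape_stage(scaled, gt_mesh, "pcl", n_samples=5000, seed=1)
        assert m2.sre == pytest.approx(m1.sre, rel=1e-9)
        assert m2.src == pytest.approx(m1.src, abs=1e-9)

    def test_gaussian_noise_sre_band(self, gt_mesh):
        """Isotropic noise of sigma=0.005 (normalized) onto a surface:
        nearest-neighbour RMS lands between the out-of-plane component
        ~sigma*sqrt(1) and the full 3D sigma*sqrt(3)."""
        rec_norm = eb.normalize_model(
            eb.sample_mesh_to_pointcloud(gt_mesh, 20_000, seed=3)
        )
        rng = np.random.default_rng(4)
        noisy = eb.PointCloud(
            rec_norm.points + rng.normal(scale=0.005, size=rec_norm.points.shape),
            normalized=True,
        )
        # gt must be dense enough that the inter-sample spacing
        # (~0.012 at 20k points) does not swamp the noise scale
        gt_norm = eb.normalize_model(
            eb.sample_mesh_to_pointcloud(gt_mesh, 200_000, seed=5)
        )
        sre = eb.compute_sre(noisy, gt_norm)
        assert 0.003 <= sre <= 0.006

    def test_cap_dropout_src(self, gt_mesh):
        """Removing a contiguous 40% cap leaves ~60% voxel coverage."""
        rec = eb.sample_mesh_to_pointcloud(gt_mesh, 20_000, seed=6)
        z = rec.points[:, 2]
        keep = z <= np.quantile(z, 0.6)
        m = eb.evaluate_shape_stage(
            eb.PointCloud(rec.points[keep]),
            gt_mesh,
            "pcl",
            n_samples=20_000,
            seed=6,
            normalize_by_gt_box=True,
        )
        assert m.src == pytest.approx(60.0, abs=5.0)

    def test_mesh_input_is_sampled(self, gt_mesh):
        m = eb.evaluate_shape_stage(gt_mesh, gt_mesh, "mesh", n_samples=5000, seed=7)
        assert m.sre == pytest.approx(0.0, abs=1e-9)
        assert m.src == 100.0
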