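import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import endobench as eb
from endobench.evaluate import perturb_pose_set
from endobench.pose_metrics import umeyama_similarity


def random_pose_set(n, seed, spread=2.0):
    rng = np.random.default_rng(seed)
    mats = np.tile(np.eye(4), (n, 1, 1))
    mats[:, :3, :3] = Rotation.random(n, rng=rng).as_matrix()
    mats[:, :3, 3] = rng.normal(scale=spread, size=(n, 3))
    return eb.PoseSet(mats)


def brute_force_ape(rec, gt):
    """Element-by-element evaluation of the APE definition."""
    per = []
    for Pr, Pg in zip(rec.matrices, gt.matrices):
        per.append(np.linalg.norm(np.linalg.inv(Pr) @ Pg - np.eye(4)))
    return float(np.sqrt(np.mean(np.square(per)))), np.array(per)


def brute_force_rpe(rec, gt):
    per = []
    for i in range(len(gt) - 1):
        rp_rec = np.linalg.inv(rec.matrices[i]) @ rec.matrices[i + 1]
        rp_gt = np.linalg.inv(gt.matrices[i]) @ gt.matrices[i + 1]
        per.append(np.linalg.norm(np.linalg.inv(rp_rec) @ rp_gt - np.eye(4)))
    return float(np.sqrt(np.mean(np.square(per)))), np.array(per)


class TestBruteForceOracle:
    @pytest.mark.parametrize("n", [2, 3, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ape_matches_explicit_loops(self, n, seed):
        rec = random_pose_set(n, seed)
        gt = random_pose_set(n, seed + 100)
        expected, per = brute_force_ape(rec, gt)
        got = eb.compute_ape(rec, gt)
        assert got.value == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(got.per_element, per, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5])
    @pytest.mark.parametrize("seed", [3, 4])
    def test_rpe_matches_explicit_loops(self, n, seed):
        rec = random_pose_set(n, seed)
        gt = random_pose_set(n, seed + 100)
        expected, per = brute_force_rpe(rec, gt)
        got = eb.compute_rpe(rec, gt)
        assert got.value == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(got.per_element, per, atol=1e-12)


class TestApe:
    def test_zero_for_identical_sets(self):
        ps = random_pose_set(10, 5)
        assert eb.compute_ape(ps, ps).value == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_translation_offset(self):
        """A 0.3 cm x-offset puts exactly one 0.3 entry in the error
        matrix, so its Frobenius norm is 0.3."""
        gt = eb.PoseSet(np.eye(4)[None])
        rec_m = np.eye(4)[None].copy()
        rec_m[0, 0, 3] = 0.3
        ape = eb.compute_ape(eb.PoseSet(rec_m), gt)
        assert ape.value == pytest.approx(0.3, abs=1e-12)

    def test_rms_aggregation(self):
        """Per-frame errors {0, 0.3} aggregate to 0.3/sqrt(2)."""
        gt = eb.PoseSet(np.tile(np.eye(4), (2, 1, 1)))
        rec_m = np.tile(np.eye(4), (2, 1, 1))
        rec_m[1, 0, 3] = 0.3
        ape = eb.compute_ape(eb.PoseSet(rec_m), gt)
        np.testing.assert_allclose(ape.per_element, [0.0, 0.3], atol=1e-15)
        assert ape.value == pytest.approx(0.3 / np.sqrt(2), abs=1e-12)

    def test_component_split_localizes_error(self):
        gt = random_pose_set(6, 7)
        rec_m = gt.matrices.copy()
        rec_m[:, :3, 3] += [0.1, 0.0, 0.0]  # translation-only corruption
        rec = eb.PoseSet(rec_m)
        assert eb.compute_ape(rec, gt, "rotation").value == pytest.approx(
            0.0, abs=1e-12
        )
        assert eb.compute_ape(rec, gt, "translation").value > 0.05

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            eb.compute_ape(random_pose_set(3, 0), random_pose_set(4, 0))

    def test_singular_matrix_rejected(self):
        bad = np.zeros((1, 4, 4))
        with pytest.raises(ValueError):
            eb.compute_ape(eb.PoseSet(bad), eb.PoseSet(np.eye(4)[None]))


class TestRpe:
    def test_zero_for_identical_sets(self):
        ps = random_pose_set(10, 6)
        assert eb.compute_rpe(ps, ps).value == pytest.approx(0.0, abs=1e-12)

    def test_global_rigid_offset_cancels(self):
        """rec = Q gt for a fixed rigid Q: relative motions cancel Q, so
        RPE = 0 while APE > 0 (without alignment)."""
        gt = random_pose_set(8, 9)
        Q = np.eye(4)
        Q[:3, :3] = Rotation.from_euler("xyz", [20, -10, 35], degrees=True).as_matrix()
        Q[:3, 3] = [0.5, -0.2, 0.9]
        rec = eb.PoseSet(np.einsum("ab,nbc->nac", Q, gt.matrices))
        assert eb.compute_rpe(rec, gt).value == pytest.approx(0.0, abs=1e-10)
        assert eb.compute_ape(rec, gt).value > 0.1

    def test_consecutive_pair_count(self):
        gt = random_pose_set(100, 11)
        rec = random_pose_set(100, 12)
        rpe = eb.compute_rpe(rec, gt, pair_mode="consecutive")
        assert len(rpe.per_element) == 99

    def test_all_pairs_count(self):
        gt = random_pose_set(10, 13)
        rpe = eb.compute_rpe(gt, gt, pair_mode="all_pairs")
        assert len(rpe.per_element) == 45

    def test_single_pose_rejected(self):
        ps = eb.PoseSet(np.eye(4)[None])
        with pytest.raises(ValueError):
            eb.compute_rpe(ps, ps)

    def test_chained_frame_error_diagnostic(self):
        """A rotation error injected at one frame and chained forward
        raises APE >10x while only one consecutive RPE pair moves —
        the signature separating drift from local noise."""
        traj = eb.make_spiral_trajectory(5.0, 0.7, 2.5, 4.0, 10.0)
        gt = eb.PoseSet(traj.matrices())
        k = len(gt) // 2
        rec = perturb_pose_set(gt, frame_error_deg=5.0, frame_k=k)
        baseline = eb.compute_ape(gt, gt).value
        _, rec_aligned = eb.align_pose_sets(rec, gt)
        ape = eb.compute_ape(rec_aligned, gt).value
        assert ape > 10 * max(baseline, 1e-6)
        rpe = eb.compute_rpe(rec, gt)  # unaligned: RPE ignores global offsets
        elevated = rpe.per_element > 1e-9
        assert elevated.sum() == 1
        assert np.flatnonzero(elevated)[0] == k - 1


class TestAlignment:
    def test_recovers_known_similarity(self):
        """Forward-transform by (s=2, 90 deg about z, t=(1,2,3)) and
        recover it exactly."""
        gt = random_pose_set(20, 20, spread=3.0)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        # rec is gt mapped into the "reconstruction frame"
        rec_m = gt.matrices.copy()
        rec_m[:, :3, :3] = np.einsum("ab,nbc->nac", Rz, gt.rotations)
        rec_m[:, :3, 3] = 2.0 * gt.centers @ Rz.T + t
        rec = eb.PoseSet(rec_m)
        result, rec_aligned = eb.align_pose_sets(rec, gt)
        # the inverse similarity: s=1/2, R=Rz^T, t=-R^T t / s
        assert result.scale == pytest.approx(0.5, abs=1e-9)
        np.testing.assert_allclose(result.rotation, Rz.T, atol=1e-9)
        np.testing.assert_allclose(
            result.translation, -0.5 * Rz.T @ t, atol=1e-9
        )
        assert result.rms_residual < 1e-9
        np.testing.assert_allclose(rec_aligned.centers, gt.centers, atol=1e-9)

    def test_identity_for_identical_sets(self):
        ps = random_pose_set(10, 21)
        result, _ = eb.align_pose_sets(ps, ps)
        assert result.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(result.translation, 0.0, atol=1e-12)

    def test_ape_invariant_under_global_similarity(self):
        """Post-alignment APE does not depend on the arbitrary frame of
        the reconstruction."""
        traj = eb.make_spiral_trajectory(5.0, 0.7, 2.5, 4.0, 10.0)
        gt = eb.PoseSet(traj.matrices())
        noisy = eb.add_jitter(traj, 0.05, 1.0, seed=1)
        rec = eb.PoseSet(noisy.matrices())
        _, aligned0 = eb.align_pose_sets(rec, gt)
        ape0 = eb.compute_ape(aligned0, gt).value
        rng = np.random.default_rng(2)
        sim = (2.7, Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        rec_moved = perturb_pose_set(rec, similarity=sim)
        _, aligned1 = eb.align_pose_sets(rec_moved, gt)
        ape1 = eb.compute_ape(aligned1, gt).value
        assert abs(ape1 - ape0) < 1e-9

    def test_coincident_centers_rejected(self):
        mats = np.tile(np.eye(4), (3, 1, 1))
        ps = eb.PoseSet(mats)
        with pytest.raises(ValueError):
            eb.align_pose_sets(ps, ps)

    def test_collinear_centers_rejected(self):
        mats = np.tile(np.eye(4), (4, 1, 1))
        mats[:, 0, 3] = [0.0, 1.0, 2.0, 3.0]
        ps = eb.PoseSet(mats)
        with pytest.raises(ValueError):
            eb.align_pose_sets(ps, ps)

    def test_umeyama_on_plain_points(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(30, 3))
        R = Rotation.random(rng=rng).as_matrix()
        dst = 1.7 * src @ R.T + [4.0, -1.0, 0.5]
        s, R_fit, t_fit = umeyama_similarity(src, dst)
        assert s == pytest.approx(1.7, abs=1e-12)
        np.testing.assert_allclose(R_fit, R, atol=1e-12)
        np.testing.assert_allclose(t_fit, [4.0, -1.0, 0.5], atol=1e-12)


class TestDecompose:
    def test_identity(self):
        P_t, P_r = eb.decompose_pose(np.eye(4))
        np.testing.assert_array_equal(P_t, np.eye(4))
        np.testing.assert_array_equal(P_r, np.eye(4))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_recomposition_exact(self, seed):
        P = random_pose_set(1, seed).matrices[0]
        P_t, P_r = eb.decompose_pose(P)
        np.testing.assert_allclose(P_t @ P_r, P, atol=1e-12)
        np.testing.assert_array_equal(P_t[:3, :3], np.eye(3))
        np.testing.assert_array_equal(P_r[:3, 3], np.zeros(3))

    def test_pure_rotation_gives_identity_translation_factor(self):
        P = np.eye(4)
        P[:3, :3] = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        P_t, _ = eb.decompose_pose(P)
        np.testing.assert_array_equal(P_t, np.eye(4))
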