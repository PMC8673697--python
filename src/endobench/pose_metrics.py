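"""Camera-pose accuracy metrics: APE and RPE.

Given matched reconstructed and ground-truth pose sets (world-from-
camera 4x4 matrices), the reconstructed set is first aligned to the
ground truth with a closed-form least-squares similarity (Umeyama) fit
on the camera centers — reconstruction pipelines recover poses only up
to a global scale, rotation and translation.  Then:

* absolute pose error::

      APE_i = || (P_i^rec)^-1 P_i^gt - I_4 ||_F,   APE = RMS_i(APE_i)

  which is sensitive to accumulated drift, and

* relative pose error, on inter-frame motions
  ``RP_ij = P_i^-1 P_j``::

      RPE_ij = || (RP_ij^rec)^-1 RP_ij^gt - I_4 ||_F,  RPE = RMS(RPE_ij)

  which cancels any global offset and so isolates local consistency.
  The default pair set is consecutive frames (j = i + 1); an all-pairs
  mode is available.

A large APE with a small RPE is the signature of a single bad frame
whose error propagates to every subsequent absolute pose.  Both metrics
can be computed on the full pose or on its translation-only /
rotation-only decomposition to localize which component fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

Component = Literal["full", "translation", "rotation"]
PairMode = Literal["consecutive", "all_pairs"]


@dataclass
class PoseSet:
    """Ordered 4x4 world-from-camera matrices with frame ids."""

    matrices: np.ndarray
    frame_ids: np.ndarray | None = None
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (4, 4):
            raise ValueError("matrices must be (N, 4, 4)")
        if len(self.matrices) < 1:
            raise ValueError("pose set must contain at least one pose")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.matrices))
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=np.int64)
            if len(self.frame_ids) != len(self.matrices):
                raise ValueError("frame_ids length mismatch")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
            if len(self.timestamps) != len(self.matrices):
                raise ValueError("timestamps length mismatch")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def centers(self) -> np.ndarray:
        return self.matrices[:, :3, 3]

    @property
    def rotations(self) -> np.ndarray:
        return self.matrices[:, :3, :3]


@dataclass
class AlignmentResult:
    """Similarity transform mapping reconstructed centers onto ground truth."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float


@dataclass
class PoseMetrics:
    """Aggregate and per-frame (or per-pair) pose errors."""

    value: float
    per_element: np.ndarray
    component: Component
    metric: str  # "APE" or "RPE"


def _check_matched(rec: PoseSet, gt: PoseSet) -> None:
    if len(rec) != len(gt):
        raise ValueError(f"pose count mismatch: {len(rec)} vs {len(gt)}")
    if not np.array_equal(rec.frame_ids, gt.frame_ids):
        raise ValueError("frame ids do not match between pose sets")


def umeyama_similarity(
    src: np.ndarray, dst: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity ``dst ~ s R src + t`` (Umeyama 1991).

    Requires at least 3 non-collinear points for a unique solution.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must both be (N, 3)")
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / n
    var_s = (xs**2).sum() / n
    if var_s < 1e-24:
        raise ValueError("degenerate geometry: source points are coincident")
    U, D, Vt = np.linalg.svd(cov)
    # guard against collinear/planar degeneracies
    if D[1] < 1e-12 * max(D[0], 1e-300):
        raise ValueError("degenerate geometry: points are collinear")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    s = float(np.trace(np.diag(D) @ S) / var_s)
    if s <= 0:
        raise ValueError("non-positive similarity scale")
    t = mu_d - s * R @ mu_s
    return s, R, t


def align_pose_sets(rec: PoseSet, gt: PoseSet) -> tuple[AlignmentResult, PoseSet]:
    """Similarity-align reconstructed poses to ground truth on camera centers.

    Centers map as ``c' = s R c + t`` and rotations as ``R' = R_a R_i``;
    returns the fit and the aligned pose set.
    """
    _check_matched(rec, gt)
    if len(rec) < 3:
        raise ValueError("need at least 3 poses for similarity alignment")
    s, R, t = umeyama_similarity(rec.centers, gt.centers)
    aligned = rec.matrices.copy()
    aligned[:, :3, :3] = np.einsum("ab,nbc->nac", R, rec.rotations)
    aligned[:, :3, 3] = (s * (rec.centers @ R.T)) + t
    residual = np.linalg.norm(aligned[:, :3, 3] - gt.centers, axis=1)
    result = AlignmentResult(
        scale=s,
        rotation=R,
        translation=t,
        rms_residual=float(np.sqrt((residual**2).mean())),
    )
    return result, PoseSet(aligned, rec.frame_ids, rec.timestamps)


def decompose_pose(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a pose into translation-only and rotation-only factors.

    ``P_t`` carries the translation with identity rotation, ``P_r`` the
    rotation with zero translation; ``P = P_t @ P_r`` exactly.
    """
    P = np.asarray(P, dtype=np.float64).reshape(4, 4)
    P_t = np.eye(4)
    P_t[:3, 3] = P[:3, 3]
    P_r = np.eye(4)
    P_r[:3, :3] = P[:3, :3]
    return P_t, P_r


def _component_matrices(mats: np.ndarray, component: Component) -> np.ndarray:
    if component == "full":
        return mats
    out = np.tile(np.eye(4), (len(mats), 1, 1))
    if component == "translation":
        out[:, :3, 3] = mats[:, :3, 3]
    elif component == "rotation":
        out[:, :3, :3] = mats[:, :3, :3]
    else:
        raise ValueError(f"unknown component {component!r}")
    return out


def _invert_rigid(mats: np.ndarray) -> np.ndarray:
    """Batch inverse; uses the rigid closed form when valid, else solve."""
    dets = np.linalg.det(mats[:, :3, :3])
    if (np.abs(dets) < 1e-12).any():
        raise ValueError("singular pose matrix")
    Rt = np.transpose(mats[:, :3, :3], (0, 2, 1))
    orth = np.abs(np.einsum("nab,nbc->nac", Rt, mats[:, :3, :3]) - np.eye(3)).max()
    if orth < 1e-9:
        inv = np.tile(np.eye(4), (len(mats), 1, 1))
        inv[:, :3, :3] = Rt
        inv[:, :3, 3] = -np.einsum("nab,nb->na", Rt, mats[:, :3, 3])
        return inv
    return np.linalg.inv(mats)


def compute_ape(
    rec_aligned: PoseSet, gt: PoseSet, component: Component = "full"
) -> PoseMetrics:
    """Absolute pose error (RMS over frames of per-frame Frobenius norms)."""
    _check_matched(rec_aligned, gt)
    rec_m = _component_matrices(rec_aligned.matrices, component)
    gt_m = _component_matrices(gt.matrices, component)
    err = np.einsum("nab,nbc->nac", _invert_rigid(rec_m), gt_m) - np.eye(4)
    per_frame = np.linalg.norm(err, axis=(1, 2))
    return PoseMetrics(
        value=float(np.sqrt((per_frame**2).mean())),
        per_element=per_frame,
        component=component,
        metric="APE",
    )


def compute_rpe(
    rec_aligned: PoseSet,
    gt: PoseSet,
    component: Component = "full",
    pair_mode: PairMode = "consecutive",
) -> PoseMetrics:
    """Relative pose error over inter-frame motions.

    ``pair_mode="consecutive"`` uses the N-1 pairs (i, i+1);
    ``"all_pairs"`` uses every ordered pair i < j.
    """
    _check_matched(rec_aligned, gt)
    n = len(gt)
    if n < 2:
        raise ValueError("RPE needs at least 2 poses")
    if pair_mode == "consecutive":
        ii = np.arange(n - 1)
        jj = ii + 1
    elif pair_mode == "all_pairs":
        ii, jj = np.triu_indices(n, k=1)
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    rec_m = _component_matrices(rec_aligned.matrices, component)
    gt_m = _component_matrices(gt.matrices, component)
    rp_rec = np.einsum("nab,nbc->nac", _invert_rigid(rec_m[ii]), rec_m[jj])
    rp_gt = np.einsum("nab,nbc->nac", _invert_rigid(gt_m[ii]), gt_m[jj])
    err = np.einsum("nab,nbc->nac", _invert_rigid(rp_rec), rp_gt) - np.eye(4)
    per_pair = np.linalg.norm(err, axis=(1, 2))
    return PoseMetrics(
        value=float(np.sqrt((per_pair**2).mean())),
        per_element=per_pair,
        component=component,
        metric="RPE",
    )
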