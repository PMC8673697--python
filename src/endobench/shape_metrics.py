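"""Shape accuracy (SRE) and completeness (SRC) metrics.

A reconstructed shape can be accurate yet cover only a sliver of the
organ, so accuracy alone is not enough.  Two complementary numbers are
computed on bounding-box-normalized, ICP-registered point clouds:

* **SRE** — root-mean-square nearest-neighbour distance from every
  reconstructed point to the ground-truth cloud.  In the unit-
  normalized box it ranges from 0 to sqrt(3) ~ 1.732 (the box
  diagonal), smaller is better.
* **SRC** — both clouds are binned into voxels (default edge 0.04 in
  normalized units) to cancel point-density differences; a ground-truth
  voxel counts as *observed* when a reconstructed occupied voxel center
  lies within a threshold (default 0.01) of its center, and SRC is the
  percentage of ground-truth voxels observed.  With the default
  threshold below the voxel edge, observedness reduces to exact voxel
  coincidence.

Meshes are Monte-Carlo sampled into point clouds first, since both
metrics are defined on point clouds.  Pipeline stages are tagged
``pcl`` (raw point cloud), ``pp-pcl`` (postprocessed) and ``mesh``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

from endobench.geometry import PointCloud, TriMesh, sample_mesh_to_pointcloud

Stage = Literal["pcl", "pp-pcl", "mesh"]

DEFAULT_VOXEL_EDGE = 0.04
DEFAULT_OBSERVED_THRESHOLD = 0.01
SRE_MAX = float(np.sqrt(3.0))


@dataclass
class VoxelGrid:
    """Occupancy set on a regular grid: index = floor(point / edge)."""

    edge: float
    occupied: np.ndarray  # (k, 3) int64, unique rows

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("voxel edge must be positive")
        self.occupied = np.asarray(self.occupied, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.occupied)

    def centers(self) -> np.ndarray:
        return (self.occupied + 0.5) * self.edge


@dataclass
class ShapeMetrics:
    """SRE (normalized units) and SRC (%) for one pipeline stage."""

    sre: float
    src: float
    stage: Stage | None = None


# ---------------------------------------------------------------------------


def _points_of(model: PointCloud | TriMesh) -> np.ndarray:
    if isinstance(model, TriMesh):
        return model.vertices
    return model.points


def normalize_model(model: PointCloud | TriMesh) -> PointCloud | TriMesh:
    """Scale the longest bounding-box edge to 1 and center the box at origin.

    Matches the usual preprocessing of reconstruction benchmarks: after
    normalization the model lives in a unit-long box regardless of the
    arbitrary scale of the reconstruction.
    """
    pts = _points_of(model)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to normalize")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    longest = float((hi - lo).max())
    if longest <= 0:
        raise ValueError("degenerate model: zero-extent bounding box")
    center = (lo + hi) / 2.0
    new_pts = (pts - center) / longest
    if isinstance(model, TriMesh):
        out = model.copy()
        out.vertices = new_pts
        out.sphere_radius = (
            None if model.sphere_radius is None else model.sphere_radius / longest
        )
        return out
    return PointCloud(new_pts, normalized=True)


def icp_register(
    rec: PointCloud,
    gt: PointCloud,
    max_iter: int = 50,
    tol: float = 1e-6,
    history: list[float] | None = None,
) -> tuple[np.ndarray, PointCloud]:
    """Point-to-point ICP of ``rec`` onto ``gt``.

    Alternates nearest-neighbour correspondence with the closed-form
    SVD rigid update until the RMS residual changes by less than ``tol``
    or ``max_iter`` is reached.  Returns the accumulated rigid 4x4
    transform and the registered cloud.  The per-iteration RMS residual
    is non-increasing; pass a list as ``history`` to collect it (one
    entry per correspondence evaluation, logged at DEBUG).
    """
    if len(rec) == 0 or len(gt) == 0:
        raise ValueError("cannot register empty point clouds")
    tree = cKDTree(gt.points)
    cur = rec.points.copy()
    T = np.eye(4)
    prev_rms = np.inf
    for it in range(max_iter):
        dist, idx = tree.query(cur, workers=-1)
        rms = float(np.sqrt((dist**2).mean()))
        if history is not None:
            history.append(rms)
        logger.debug("ICP iteration %d: RMS residual %.3e", it, rms)
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        src_mu = cur.mean(axis=0)
        dst = gt.points[idx]
        dst_mu = dst.mean(axis=0)
        H = (cur - src_mu).T @ (dst - dst_mu)
        U, _, Vt = np.linalg.svd(H)
        S = np.eye(3)
        if np.linalg.det(Vt.T @ U.T) < 0:
            S[2, 2] = -1.0
        R = Vt.T @ S @ U.T
        t = dst_mu - R @ src_mu
        cur = cur @ R.T + t
        step = np.eye(4)
        step[:3, :3] = R
        step[:3, 3] = t
        T = step @ T
    return T, PointCloud(cur, normalized=rec.normalized)


def compute_sre(rec: PointCloud, gt: PointCloud) -> float:
    """RMS nearest-neighbour distance from reconstructed to ground truth."""
    if len(rec) == 0 or len(gt) == 0:
        raise ValueError("SRE needs non-empty point clouds")
    dist, _ = cKDTree(gt.points).query(rec.points, workers=-1)
    return float(np.sqrt((dist**2).mean()))


def voxelize(pcl: PointCloud, edge: float = DEFAULT_VOXEL_EDGE) -> VoxelGrid:
    """Bin points into voxels of the given edge; duplicates collapse."""
    if edge <= 0:
        raise ValueError("voxel edge must be positive")
    if len(pcl) == 0:
        return VoxelGrid(edge, np.empty((0, 3), dtype=np.int64))
    idx = np.floor(pcl.points / edge).astype(np.int64)
    return VoxelGrid(edge, np.unique(idx, axis=0))


def compute_src(
    rec: PointCloud,
    gt: PointCloud,
    edge: float = DEFAULT_VOXEL_EDGE,
    threshold: float = DEFAULT_OBSERVED_THRESHOLD,
    strict_literal: bool = False,
) -> float:
    """Shape reconstruction coverage, in percent.

    Both clouds are voxelized at ``edge``; a reconstructed voxel
    *observes* a ground-truth voxel when their centers are within
    ``threshold``.  The default numerator counts distinct observed
    ground-truth voxels, which caps SRC at 100% for any threshold;
    ``strict_literal=True`` instead counts observed reconstructed
    voxels (identical at the defaults, where threshold < edge implies
    one-to-one coincidence).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gt_grid = voxelize(gt, edge)
    if len(gt_grid) == 0:
        raise ValueError("ground-truth cloud is empty")
    rec_grid = voxelize(rec, edge)
    if len(rec_grid) == 0:
        return 0.0
    tree = cKDTree(gt_grid.centers())
    dist, idx = tree.query(rec_grid.centers(), workers=-1)
    observed = dist <= threshold
    if strict_literal:
        matched = int(observed.sum())
    else:
        matched = len(np.unique(idx[observed]))
    return 100.0 * matched / len(gt_grid)


def evaluate_shape_stage(
    rec_model: PointCloud | TriMesh,
    gt_mesh: TriMesh,
    stage: Stage,
    n_samples: int = 50_000,
    edge: float = DEFAULT_VOXEL_EDGE,
    threshold: float = DEFAULT_OBSERVED_THRESHOLD,
    seed: int = 0,
    icp_max_iter: int = 50,
    icp_tol: float = 1e-6,
    normalize_by_gt_box: bool = False,
) -> ShapeMetrics:
    """Full shape-scoring chain for one pipeline stage.

    Mesh inputs (the reconstruction's, and always the ground truth) are
    Monte-Carlo sampled to point clouds, both models are bounding-box
    normalized, the reconstruction is ICP-registered onto the ground
    truth, and SRE/SRC are computed.

    ``normalize_by_gt_box=True`` scales the reconstruction by the
    ground-truth box instead of its own — useful for partial
    reconstructions, whose own bounding box would inflate their scale.
    """
    if isinstance(rec_model, TriMesh):
        rec_cloud = sample_mesh_to_pointcloud(rec_model, n_samples, seed=seed)
    else:
        rec_cloud = rec_model
    gt_cloud = sample_mesh_to_pointcloud(gt_mesh, n_samples, seed=seed)

    gt_pts = gt_cloud.points
    lo, hi = gt_pts.min(axis=0), gt_pts.max(axis=0)
    gt_scale = float((hi - lo).max())
    gt_center = (lo + hi) / 2.0
    gt_norm = PointCloud((gt_pts - gt_center) / gt_scale, normalized=True)
    if normalize_by_gt_box:
        rec_norm = PointCloud(
            (rec_cloud.points - gt_center) / gt_scale, normalized=True
        )
    else:
        rec_norm = normalize_model(rec_cloud)
    _, rec_reg = icp_register(rec_norm, gt_norm, max_iter=icp_max_iter, tol=icp_tol)
    return ShapeMetrics(
        sre=compute_sre(rec_reg, gt_norm),
        src=compute_src(rec_reg, gt_norm, edge=edge, threshold=threshold),
        stage=stage,
    )
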