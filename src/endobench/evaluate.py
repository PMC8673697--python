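"""End-to-end evaluation of a reconstruction against a synthesis bundle.

Mirrors how a monocular-endoscopy reconstruction pipeline is actually
assessed, stage by stage:

(a) camera poses: similarity-align to ground truth, then APE and RPE on
    the full pose and its translation/rotation decompositions, plus
    SRE/SRC of the raw point cloud;
(b) postprocessed point cloud: SRE/SRC;
(c) mesh model: Monte-Carlo sampled, then SRE/SRC;
(d) texture: the auxiliary video and ground-truth auxiliary model are
    referenced in the report for visual side-by-side inspection — no
    quantitative texture score is invented.

Also provides :func:`make_perturbed_fixture`, which manufactures a
synthetic "reconstruction" from a ground-truth bundle with controlled
noise, contiguous-cap dropout, a global similarity offset and an
optional single-frame rotation error that propagates to all later
frames (chained drift) — the scenarios the pose metrics are designed to
tell apart.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from endobench.geometry import (
    PointCloud,
    TriMesh,
    load_mesh,
    load_pointcloud,
    sample_mesh_to_pointcloud,
    save_mesh,
    save_pointcloud,
)
from endobench.pose_metrics import (
    PoseSet,
    align_pose_sets,
    compute_ape,
    compute_rpe,
)
from endobench.shape_metrics import (
    DEFAULT_OBSERVED_THRESHOLD,
    DEFAULT_VOXEL_EDGE,
    ShapeMetrics,
    evaluate_shape_stage,
)
from endobench.synthesis import SynthesisBundle, read_pose_file, write_pose_file

logger = logging.getLogger(__name__)

STAGES = ("pcl", "pp-pcl", "mesh")

#: Minimal structural schema for serialized reports: maps dotted paths to
#: the required python type ("stage" entries may also be None for absent
#: stages).
REPORT_SCHEMA: dict[str, type] = {
    "tool_version": str,
    "pose_metrics": dict,
    "shape_metrics": dict,
    "texture_inspection": dict,
    "config": dict,
}


@dataclass
class ReconstructionArtifacts:
    """Paths to a pipeline's staged outputs; absent stages are ``None``."""

    poses: Path | None = None
    pcl: Path | None = None
    pp_pcl: Path | None = None
    mesh: Path | None = None
    textured_model: Path | None = None
    camera_from_world: bool = False  # invert pose matrices on load

    def __post_init__(self) -> None:
        if all(
            p is None for p in (self.poses, self.pcl, self.pp_pcl, self.mesh)
        ):
            raise ValueError("at least one reconstruction stage must be present")

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "ReconstructionArtifacts":
        """Discover conventionally named artifacts in a directory."""
        path = Path(path)

        def first(*names: str) -> Path | None:
            for name in names:
                p = path / name
                if p.exists():
                    return p
            return None

        return cls(
            poses=first("poses.txt", "camera_poses.txt"),
            pcl=first("pcl.ply"),
            pp_pcl=first("pp_pcl.ply", "pp-pcl.ply"),
            mesh=first("mesh.ply", "mesh.obj"),
            textured_model=first("textured.obj", "textured.ply"),
            **kwargs,
        )


@dataclass
class EvaluationReport:
    """All metrics from one evaluation run; absent stages stay ``None``."""

    pose_metrics: dict[str, float] | None
    shape_metrics: dict[str, ShapeMetrics | None]
    texture_inspection: dict[str, str]
    config: dict
    tool_version: str = ""

    def to_dict(self) -> dict:
        shape = {
            stage: None if m is None else {"SRE": m.sre, "SRC": m.src}
            for stage, m in self.shape_metrics.items()
        }
        return {
            "tool_version": self.tool_version,
            "pose_metrics": self.pose_metrics or {},
            "shape_metrics": shape,
            "texture_inspection": self.texture_inspection,
            "config": self.config,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def write_csv(self, path: str | Path) -> Path:
        """Per-stage CSV rows: stage, SRE, SRC (absent stages marked)."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stage", "SRE", "SRC_percent"])
            for stage, m in self.shape_metrics.items():
                if m is None:
                    writer.writerow([stage, "absent", "absent"])
                else:
                    writer.writerow([stage, f"{m.sre:.6g}", f"{m.src:.4f}"])
        return path


def validate_report(payload: dict) -> None:
    """Check a serialized report against :data:`REPORT_SCHEMA`.

    Raises ``ValueError`` on a missing key, wrong type, or a stage entry
    that is neither absent (None) nor an {SRE, SRC} mapping.
    """
    for key, typ in REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for stage, entry in payload["shape_metrics"].items():
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if entry is None:
            continue
        if set(entry) != {"SRE", "SRC"} or not all(
            isinstance(v, (int, float)) for v in entry.values()
        ):
            raise ValueError(f"stage {stage!r} entry must map SRE/SRC to numbers")
    for key, value in payload["pose_metrics"].items():
        if not isinstance(value, (int, float)):
            raise ValueError(f"pose metric {key!r} must be a number")


# ---------------------------------------------------------------------------


def _load_pose_set(path: Path, camera_from_world: bool) -> PoseSet:
    ps = read_pose_file(path)
    if camera_from_world:
        ps = PoseSet(np.linalg.inv(ps.matrices), ps.frame_ids, ps.timestamps)
    return ps


def evaluate_all(
    artifacts: ReconstructionArtifacts,
    gt_bundle: SynthesisBundle,
    n_samples: int = 50_000,
    edge: float = DEFAULT_VOXEL_EDGE,
    threshold: float = DEFAULT_OBSERVED_THRESHOLD,
    seed: int = 0,
    rpe_pair_mode: str = "consecutive",
    normalize_by_gt_box: bool = False,
) -> EvaluationReport:
    """Run the full staged evaluation; see the module docstring."""
    for name in ("phantom_model", "auxiliary_model", "pose_file"):
        p = getattr(gt_bundle, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"ground-truth bundle is missing {name}: {p}")
    gt_mesh = load_mesh(gt_bundle.phantom_model)

    pose_metrics: dict[str, float] | None = None
    if artifacts.poses is not None:
        logger.info("stage (a): aligning poses and computing APE/RPE")
        rec = _load_pose_set(Path(artifacts.poses), artifacts.camera_from_world)
        gt = read_pose_file(gt_bundle.pose_file)
        _, rec_aligned = align_pose_sets(rec, gt)
        pose_metrics = {}
        for component in ("full", "translation", "rotation"):
            pose_metrics[f"APE_{component}"] = compute_ape(
                rec_aligned, gt, component
            ).value
            pose_metrics[f"RPE_{component}"] = compute_rpe(
                rec_aligned, gt, component, pair_mode=rpe_pair_mode
            ).value

    shape: dict[str, ShapeMetrics | None] = {}
    stage_paths = {
        "pcl": artifacts.pcl,
        "pp-pcl": artifacts.pp_pcl,
        "mesh": artifacts.mesh,
    }
    for stage, path in stage_paths.items():
        if path is None:
            shape[stage] = None
            continue
        logger.info("scoring stage %s from %s", stage, path)
        rec_model: PointCloud | TriMesh
        if stage == "mesh":
            rec_model = load_mesh(path)
        else:
            rec_model = load_pointcloud(path)
        shape[stage] = evaluate_shape_stage(
            rec_model,
            gt_mesh,
            stage,  # type: ignore[arg-type]
            n_samples=n_samples,
            edge=edge,
            threshold=threshold,
            seed=seed,
            normalize_by_gt_box=normalize_by_gt_box,
        )

    from endobench import __version__

    texture = {
        "auxiliary_video": str(gt_bundle.auxiliary_video),
        "auxiliary_model": str(gt_bundle.auxiliary_model),
        "note": "compare the reconstructed textured model against the "
        "auxiliary model grid by visual inspection",
    }
    if artifacts.textured_model is not None:
        texture["reconstructed_textured_model"] = str(artifacts.textured_model)
    return EvaluationReport(
        pose_metrics=pose_metrics,
        shape_metrics=shape,
        texture_inspection=texture,
        config={
            "n_samples": n_samples,
            "voxel_edge": edge,
            "observed_threshold": threshold,
            "seed": seed,
            "rpe_pair_mode": rpe_pair_mode,
            "normalize_by_gt_box": normalize_by_gt_box,
        },
        tool_version=__version__,
    )


# ---------------------------------------------------------------------------
# perturbation fixtures


def perturb_pose_set(
    gt: PoseSet,
    similarity: tuple[float, np.ndarray, np.ndarray] | None = None,
    frame_error_deg: float = 0.0,
    frame_k: int | None = None,
) -> PoseSet:
    """Apply a global similarity and/or a chained single-frame rotation error.

    The frame error multiplies every pose from frame ``k`` onward by a
    fixed world-side rotation about frame k's camera axes, emulating an
    estimator that mis-tracked one frame and chained the error forward.
    """
    mats = gt.matrices.copy()
    if frame_error_deg != 0.0:
        if frame_k is None:
            frame_k = len(mats) // 2
        E = np.eye(4)
        E[:3, :3] = Rotation.from_euler("y", frame_error_deg, degrees=True).as_matrix()
        Pk = mats[frame_k]
        D = Pk @ E @ np.linalg.inv(Pk)
        mats[frame_k:] = np.einsum("ab,nbc->nac", D, mats[frame_k:])
    if similarity is not None:
        s, R, t = similarity
        R = np.asarray(R, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        mats[:, :3, :3] = np.einsum("ab,nbc->nac", R, mats[:, :3, :3])
        mats[:, :3, 3] = s * (mats[:, :3, 3] @ R.T) + t
    return PoseSet(mats, gt.frame_ids, gt.timestamps)


def make_perturbed_fixture(
    gt_bundle: SynthesisBundle,
    out_dir: str | Path,
    sigma: float = 0.0,
    dropout: float = 0.0,
    similarity: tuple[float, np.ndarray, np.ndarray] | None = None,
    frame_error_deg: float = 0.0,
    frame_k: int | None = None,
    n_points: int = 20_000,
    seed: int = 0,
) -> ReconstructionArtifacts:
    """Manufacture a controlled synthetic reconstruction from ground truth.

    ``sigma`` is isotropic Gaussian noise in normalized units (fraction
    of the phantom's longest bounding-box edge); ``dropout`` removes a
    contiguous surface cap containing that fraction of the points (the
    failure mode of a pipeline that never saw part of the organ).  The
    pose file gets the same global ``similarity`` plus the optional
    chained frame error.  Everything is deterministic under ``seed``.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gt_mesh = load_mesh(gt_bundle.phantom_model)
    cloud = sample_mesh_to_pointcloud(gt_mesh, n_points, seed=seed)
    pts = cloud.points
    scale = float((pts.max(axis=0) - pts.min(axis=0)).max())

    if dropout > 0.0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        score = pts @ direction
        keep = score <= np.quantile(score, 1.0 - dropout)
        pts = pts[keep]
    if sigma > 0.0:
        pts = pts + rng.normal(scale=sigma * scale, size=pts.shape)

    if similarity is not None:
        s, R, t = similarity
        pts = s * (pts @ np.asarray(R).T) + np.asarray(t)

    pcl_path = save_pointcloud(PointCloud(pts), out_dir / "pcl.ply")
    pp_path = save_pointcloud(PointCloud(pts), out_dir / "pp_pcl.ply")

    mesh = gt_mesh.copy()
    if sigma > 0.0:
        mesh.vertices = mesh.vertices + rng.normal(
            scale=sigma * scale, size=mesh.vertices.shape
        )
        mesh.sphere_radius = None
    if similarity is not None:
        s, R, t = similarity
        mesh.vertices = s * (mesh.vertices @ np.asarray(R).T) + np.asarray(t)
        mesh.sphere_radius = None
    mesh_path = save_mesh(mesh, out_dir / "mesh.obj")

    gt_poses = read_pose_file(gt_bundle.pose_file)
    rec_poses = perturb_pose_set(gt_poses, similarity, frame_error_deg, frame_k)
    poses_path = write_pose_file(rec_poses, out_dir / "poses.txt")

    return ReconstructionArtifacts(
        poses=poses_path, pcl=pcl_path, pp_pcl=pp_path, mesh=mesh_path
    )
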