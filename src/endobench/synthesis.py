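"""One-shot dataset synthesis and the extensive benchmark groups.

A single synthesis run scans a textured phantom with a virtual
endoscope and writes five artifacts:

* ``main_video/`` — PNG frames of the vascular-textured phantom;
* ``auxiliary_video/`` — PNG frames of the *same* scan over the same
  geometry retextured with the multi-precision grid (for judging
  texture-mapping quality against known coordinates);
* ``phantom_model.obj`` and ``auxiliary_model.obj`` — ground-truth
  meshes with UVs;
* ``camera_poses.txt`` — ground-truth world-from-camera pose per frame.

The lossless PNG frame directory is the canonical "video"; an MP4 is
written additionally when an ffmpeg backend is importable.

The pose text file is TUM-trajectory compatible with a leading frame
index column::

    frame_index timestamp tx ty tz qx qy qz qw

(translation in cm, scalar-last unit quaternion, ``#`` comments).

``make_extensive_dataset`` reproduces the four benchmark groups: A —
trajectory type (spiral vs sine); B — trajectory spacings 0.2/0.3/0.4/
0.7 cm; C — imaging distances 2.0/2.5/3.5/4.0 cm; D — deformation
levels 0/0.2/0.5/1.0 at 0.2 Hz; all on the 10 cm sphere phantom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from endobench.deformation import DeformationProfile, make_radial_profile
from endobench.geometry import TriMesh, load_mesh, make_sphere_phantom, save_mesh
from endobench.render import Frame, RenderSettings, render_video
from endobench.pose_metrics import PoseSet
from endobench.texture import (
    GridParams,
    VascularParams,
    make_auxiliary_grid_texture,
    make_preset_base_texture,
    synthesize_vascular_texture,
)
from endobench.trajectory import (
    Trajectory,
    add_jitter,
    intrinsics_from_fov,
    make_sine_trajectory,
    make_spiral_trajectory,
)

CONFIG_SCHEMA_VERSION = 1

GROUP_B_SPACINGS_CM = (0.2, 0.3, 0.4, 0.7)
GROUP_C_DISTANCES_CM = (2.0, 2.5, 3.5, 4.0)
GROUP_D_LEVELS = (0.0, 0.2, 0.5, 1.0)
GROUP_D_FREQUENCY_HZ = 0.2


class PoseFileError(ValueError):
    """Raised for malformed pose files, with the offending line number."""


@dataclass
class DeformationConfig:
    """Preset radial-bulge deformation profile parameters."""

    enabled: bool = False
    level: float = 0.0
    center_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_cm: float = 2.5
    max_displacement_cm: float = 1.0
    frequency_hz: float = GROUP_D_FREQUENCY_HZ

    def __post_init__(self) -> None:
        self.center_direction = tuple(self.center_direction)


@dataclass
class SynthesisConfig:
    """Everything needed to reproduce one synthesis run from a seed."""

    # phantom
    phantom_diameter_cm: float = 10.0
    phantom_subdivisions: int = 4
    phantom_mesh_path: str | None = None  # import an OBJ/PLY instead
    # textures
    texture_width: int = 512
    texture_height: int = 512
    vascular: VascularParams = field(default_factory=VascularParams)
    grid: GridParams = field(default_factory=GridParams)
    # trajectory
    trajectory_type: str = "spiral"
    spacing_cm: float = 0.7
    imaging_distance_cm: float = 2.5
    velocity_cm_s: float = 1.0
    frame_rate_hz: float = 30.0
    polar_range: tuple[float, float] = (0.05 * np.pi, 0.95 * np.pi)
    jitter_position_cm: float = 0.0
    jitter_rotation_deg: float = 0.0
    # deformation
    deformation: DeformationConfig = field(default_factory=DeformationConfig)
    # camera / render
    width_px: int = 200
    height_px: int = 200
    fov_deg: float = 110.0
    light_intensity: float = 9.0
    exposure: float = 1.0
    write_mp4: bool = False
    # bookkeeping
    master_seed: int = 0
    output_dir: str = "synthesis_out"
    schema_version: int = CONFIG_SCHEMA_VERSION

    # -- YAML --------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthesisConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["vascular"] = VascularParams(**payload.get("vascular", {}))
        grid = payload.get("grid", {})
        grid.pop("charset", None)  # charset is fixed by the embedded font
        payload["grid"] = GridParams(**grid)
        payload["deformation"] = DeformationConfig(**payload.get("deformation", {}))
        if "polar_range" in payload:
            payload["polar_range"] = tuple(payload["polar_range"])
        return cls(**payload)


@dataclass
class SynthesisBundle:
    """The five artifacts of one synthesis run."""

    main_video: Path
    auxiliary_video: Path
    phantom_model: Path
    auxiliary_model: Path
    pose_file: Path

    def artifacts(self) -> tuple[Path, ...]:
        return (
            self.main_video,
            self.auxiliary_video,
            self.phantom_model,
            self.auxiliary_model,
            self.pose_file,
        )


# ---------------------------------------------------------------------------
# seeds


def split_seed(master_seed: int, n: int = 4) -> list[int]:
    """Fan a master seed out to per-subsystem seeds (< 2**31).

    Fixed rule (SeedSequence state expansion) so the texture, jitter and
    sampling subsystems are independently reproducible.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


# ---------------------------------------------------------------------------
# pose file IO


def write_pose_file(traj: Trajectory | PoseSet, path: str | Path) -> Path:
    """Write poses in the TUM-compatible dialect (see module docstring)."""
    path = Path(path)
    if isinstance(traj, Trajectory):
        mats = traj.matrices()
        ids = [p.frame_index for p in traj.poses]
        times = [p.timestamp_s for p in traj.poses]
    else:
        mats = traj.matrices
        ids = list(traj.frame_ids)
        times = (
            list(traj.timestamps)
            if traj.timestamps is not None
            else [float(i) for i in ids]
        )
    lines = [
        "# endobench camera poses (world-from-camera)",
        "# frame_index timestamp tx ty tz qx qy qz qw",
    ]
    for k in range(len(mats)):
        q = Rotation.from_matrix(mats[k, :3, :3]).as_quat()  # xyzw
        q = q / np.linalg.norm(q)
        t = mats[k, :3, 3]
        lines.append(
            f"{ids[k]} {times[k]:.17g} "
            f"{t[0]:.17g} {t[1]:.17g} {t[2]:.17g} "
            f"{q[0]:.17g} {q[1]:.17g} {q[2]:.17g} {q[3]:.17g}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pose_file(path: str | Path) -> PoseSet:
    """Read the pose dialect back into a :class:`PoseSet`.

    Raises :class:`PoseFileError` (with the line number) on malformed
    or non-finite records.
    """
    path = Path(path)
    ids, times, mats = [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 9:
            raise PoseFileError(
                f"{path}:{lineno}: expected 9 fields, got {len(parts)}"
            )
        try:
            vals = [float(p) for p in parts[1:]]
            idx = int(parts[0])
        except ValueError as exc:
            raise PoseFileError(f"{path}:{lineno}: {exc}") from exc
        if not np.isfinite(vals).all():
            raise PoseFileError(f"{path}:{lineno}: non-finite value")
        t, trans, quat = vals[0], vals[1:4], np.asarray(vals[4:8])
        norm = np.linalg.norm(quat)
        if abs(norm - 1.0) > 1e-6:
            raise PoseFileError(
                f"{path}:{lineno}: quaternion norm {norm:.6f} is not 1"
            )
        T = np.eye(4)
        T[:3, :3] = Rotation.from_quat(quat / norm).as_matrix()
        T[:3, 3] = trans
        ids.append(idx)
        times.append(t)
        mats.append(T)
    if not mats:
        raise PoseFileError(f"{path}: no pose records")
    return PoseSet(np.stack(mats), np.asarray(ids), np.asarray(times))


# ---------------------------------------------------------------------------
# synthesis


def _build_phantom(config: SynthesisConfig) -> TriMesh:
    if config.phantom_mesh_path is not None:
        return load_mesh(config.phantom_mesh_path)
    return make_sphere_phantom(
        config.phantom_diameter_cm, config.phantom_subdivisions
    )


def _build_trajectory(config: SynthesisConfig, jitter_seed: int) -> Trajectory:
    radius = config.phantom_diameter_cm / 2.0
    maker = {
        "spiral": make_spiral_trajectory,
        "sine": make_sine_trajectory,
    }.get(config.trajectory_type)
    if maker is None:
        raise ValueError(f"unknown trajectory type {config.trajectory_type!r}")
    traj = maker(
        radius,
        config.spacing_cm,
        config.imaging_distance_cm,
        config.velocity_cm_s,
        config.frame_rate_hz,
        tuple(config.polar_range),
    )
    if config.jitter_position_cm > 0 or config.jitter_rotation_deg > 0:
        traj = add_jitter(
            traj,
            config.jitter_position_cm,
            config.jitter_rotation_deg,
            seed=jitter_seed,
        )
    return traj


def _build_profile(
    config: SynthesisConfig, mesh: TriMesh
) -> DeformationProfile | None:
    dc = config.deformation
    if not dc.enabled:
        return None
    direction = np.asarray(dc.center_direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    center_vertex = int(np.argmax(mesh.vertices @ direction))
    return make_radial_profile(
        mesh,
        center_vertex,
        dc.radius_cm,
        dc.max_displacement_cm,
        dc.frequency_hz,
    )


def _write_frames(frames: list[Frame], directory: Path, write_mp4: bool) -> Path:
    import imageio.v3 as iio

    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        iio.imwrite(directory / f"frame_{frame.frame_index:06d}.png", frame.image)
    if write_mp4:
        try:
            import imageio

            with imageio.get_writer(
                directory.with_suffix(".mp4"), fps=30, codec="libx264"
            ) as writer:
                for frame in frames:
                    writer.append_data(frame.image)
        except Exception:
            pass  # MP4 is a convenience copy; the PNG directory is canonical
    return directory


def synthesize(config: SynthesisConfig) -> SynthesisBundle:
    """Run one synthesis: main + auxiliary videos and three ground truths.

    The auxiliary video repeats the *identical* trajectory, timestamps
    and deformation over the same geometry with the grid texture, so the
    two videos are frame-aligned.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    texture_seed, jitter_seed, _, _ = split_seed(config.master_seed)

    phantom = _build_phantom(config)
    base = make_preset_base_texture(
        config.texture_width, config.texture_height, seed=texture_seed
    )
    vascular = dataclasses.replace(config.vascular, seed=texture_seed)
    main_tex, _ = synthesize_vascular_texture(base, vascular)
    aux_tex = make_auxiliary_grid_texture(
        config.texture_width, config.texture_height, config.grid
    )
    traj = _build_trajectory(config, jitter_seed)
    profile = _build_profile(config, phantom)
    level = config.deformation.level if profile is not None else 0.0

    settings = RenderSettings(
        intrinsics=intrinsics_from_fov(
            config.width_px, config.height_px, config.fov_deg
        ),
        light_intensity=config.light_intensity,
        exposure=config.exposure,
    )
    main_frames = render_video(phantom, profile, level, main_tex, traj, settings)
    aux_frames = render_video(phantom, profile, level, aux_tex, traj, settings)

    bundle = SynthesisBundle(
        main_video=_write_frames(main_frames, out / "main_video", config.write_mp4),
        auxiliary_video=_write_frames(
            aux_frames, out / "auxiliary_video", config.write_mp4
        ),
        phantom_model=save_mesh(phantom, out / "phantom_model.obj"),
        auxiliary_model=save_mesh(phantom, out / "auxiliary_model.obj"),
        pose_file=write_pose_file(traj, out / "camera_poses.txt"),
    )
    main_tex.save(out / "main_texture.png")
    aux_tex.save(out / "auxiliary_texture.png")
    config.to_yaml(out / "config.yaml")
    return bundle


def make_extensive_dataset(
    base_config: SynthesisConfig, group: str
) -> list[SynthesisBundle]:
    """Generate one benchmark group (A, B, C or D) of synthesis runs.

    Every run uses the 10 cm sphere phantom; the group's key variable is
    swept while everything else stays at ``base_config``.
    """
    group = group.upper()
    base = dataclasses.replace(base_config, phantom_diameter_cm=10.0)
    out = Path(base.output_dir)
    variants: list[tuple[str, SynthesisConfig]] = []
    if group == "A":
        for kind in ("spiral", "sine"):
            variants.append(
                (f"trajectory_{kind}", dataclasses.replace(base, trajectory_type=kind))
            )
    elif group == "B":
        for s in GROUP_B_SPACINGS_CM:
            variants.append(
                (f"spacing_{s:.1f}cm", dataclasses.replace(base, spacing_cm=s))
            )
    elif group == "C":
        for d in GROUP_C_DISTANCES_CM:
            variants.append(
                (
                    f"distance_{d:.1f}cm",
                    dataclasses.replace(base, imaging_distance_cm=d),
                )
            )
    elif group == "D":
        for lv in GROUP_D_LEVELS:
            deform = dataclasses.replace(
                base.deformation,
                enabled=True,
                level=lv,
                frequency_hz=GROUP_D_FREQUENCY_HZ,
            )
            variants.append(
                (f"deformation_{int(round(lv * 100))}pct",
                 dataclasses.replace(base, deformation=deform))
            )
    else:
        raise ValueError(f"unknown dataset group {group!r}; expected A, B, C or D")

    bundles = []
    for name, cfg in variants:
        cfg = dataclasses.replace(
            cfg, output_dir=str(out / f"group_{group}" / name)
        )
        bundles.append(synthesize(cfg))
    return bundles
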