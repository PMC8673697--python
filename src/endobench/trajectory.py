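"""Endoscope camera trajectories over a spherical lumen.

Two clinically motivated scan patterns are provided:

* **spiral** — the scope rotates continuously while advancing, so the
  viewed surface point traces a spherical spiral from pole to pole with
  a fixed arc distance (*trajectory spacing*) between successive turns;
* **sine** — alternating meridian sweeps (dome to neck and back) with a
  small azimuth step between sweeps, covering the full 360 degrees; the
  flattened pattern looks like a sine wave.

The camera sits *inside* the lumen at ``(R - d)`` from the center, where
``R`` is the sphere radius and ``d`` the imaging distance, and looks
radially outward at the wall.  Poses are sampled by arc length so that
consecutive camera centers are ``velocity / frame_rate`` apart.

Convention: right-handed camera frame, +Z forward (toward the wall),
+Y the meridian tangent (direction of increasing polar angle), world-
from-camera 4x4 matrices, translations in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

DEFAULT_POLAR_RANGE = (0.05 * np.pi, 0.95 * np.pi)
_JITTER_SMOOTH_WINDOW = 5


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics; focal length derived from the horizontal FOV."""

    width_px: int
    height_px: int
    fov_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg < 180.0:
            raise ValueError(f"fov_deg must be in (0, 180), got {self.fov_deg}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")

    @property
    def focal_px(self) -> float:
        return (self.width_px / 2.0) / math.tan(math.radians(self.fov_deg) / 2.0)

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


def intrinsics_from_fov(
    width_px: int, height_px: int, fov_deg: float
) -> CameraIntrinsics:
    """Build intrinsics with ``focal_px = (width/2) / tan(fov/2)``."""
    return CameraIntrinsics(width_px, height_px, fov_deg)


@dataclass
class CameraPose:
    """One timestamped world-from-camera rigid transform."""

    T: np.ndarray
    frame_index: int
    timestamp_s: float

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64).reshape(4, 4)

    @property
    def R(self) -> np.ndarray:
        return self.T[:3, :3]

    @property
    def t(self) -> np.ndarray:
        return self.T[:3, 3]


@dataclass
class Trajectory:
    """Ordered camera poses plus the scan metadata that produced them."""

    poses: list[CameraPose]
    kind: str = "custom"
    spacing_cm: float | None = None
    imaging_distance_cm: float | None = None
    velocity_cm_s: float | None = None
    frame_rate_hz: float | None = None

    def __len__(self) -> int:
        return len(self.poses)

    def matrices(self) -> np.ndarray:
        return np.stack([p.T for p in self.poses])

    def centers(self) -> np.ndarray:
        return np.stack([p.t for p in self.poses])

    def timestamps(self) -> np.ndarray:
        return np.array([p.timestamp_s for p in self.poses])


# ---------------------------------------------------------------------------
# construction helpers


def _surface_direction(phi: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Unit vector to the viewed surface point at polar phi, azimuth lam."""
    sp = np.sin(phi)
    return np.stack([sp * np.cos(lam), sp * np.sin(lam), np.cos(phi)], axis=-1)


def _meridian_tangent(phi: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """d q-hat / d phi — the camera up (+Y, 'down the scan') direction."""
    cp = np.cos(phi)
    return np.stack([cp * np.cos(lam), cp * np.sin(lam), -np.sin(phi)], axis=-1)


def _poses_from_angles(
    phi: np.ndarray,
    lam: np.ndarray,
    sphere_radius: float,
    imaging_distance: float,
    frame_rate: float,
) -> list[CameraPose]:
    q = _surface_direction(phi, lam)
    y_axis = _meridian_tangent(phi, lam)
    z_axis = q  # forward: radially outward, toward the wall
    x_axis = np.cross(y_axis, z_axis)
    centers = (sphere_radius - imaging_distance) * q
    poses = []
    for k in range(len(phi)):
        T = np.eye(4)
        T[:3, 0] = x_axis[k]
        T[:3, 1] = y_axis[k]
        T[:3, 2] = z_axis[k]
        T[:3, 3] = centers[k]
        poses.append(CameraPose(T, frame_index=k, timestamp_s=k / frame_rate))
    return poses


def _resample_by_arclength(
    param_dense: np.ndarray,
    centers_dense: np.ndarray,
    step: float,
) -> np.ndarray:
    """Parameter values at which the dense polyline arc length hits k*step."""
    seg = np.linalg.norm(np.diff(centers_dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_frames = max(int(np.floor(total / step)) + 1, 2)
    targets = np.arange(n_frames) * step
    targets = targets[targets <= total]
    return np.interp(targets, s, param_dense)


def _validate_scan_args(
    sphere_radius: float, spacing: float, imaging_distance: float,
    velocity: float, frame_rate: float,
) -> None:
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    if imaging_distance >= sphere_radius:
        raise ValueError(
            f"imaging_distance {imaging_distance} must be smaller than the "
            f"sphere radius {sphere_radius} (camera must stay inside the lumen)"
        )
    if imaging_distance <= 0:
        raise ValueError("imaging_distance must be positive")
    if not 0 < spacing < np.pi * sphere_radius:
        raise ValueError("spacing must be in (0, pi * radius)")
    if velocity <= 0 or frame_rate <= 0:
        raise ValueError("velocity and frame_rate must be positive")


def make_spiral_trajectory(
    sphere_radius: float,
    spacing: float,
    imaging_distance: float,
    velocity: float,
    frame_rate: float,
    polar_range: tuple[float, float] = DEFAULT_POLAR_RANGE,
) -> Trajectory:
    """Spiral scan: azimuth advances by one turn per ``spacing`` of polar arc.

    The viewed surface point is ``R * q(phi)`` with azimuth
    ``lambda(phi) = 2 pi R phi / spacing``, so neighboring turns are
    ``spacing`` apart on the sphere.  Frames are spaced by numeric
    arc-length integration so consecutive camera centers are
    ``velocity / frame_rate`` apart.
    """
    _validate_scan_args(sphere_radius, spacing, imaging_distance, velocity, frame_rate)
    phi0, phi1 = polar_range
    if not 0.0 <= phi0 < phi1 <= np.pi:
        raise ValueError("polar_range must satisfy 0 <= lo < hi <= pi")
    turn_rate = 2.0 * np.pi * sphere_radius / spacing  # d lambda / d phi

    # dense parametrization for arc-length integration
    r_cam = sphere_radius - imaging_distance
    approx_len = r_cam * turn_rate * (phi1 - phi0)  # ~ total swept arc
    n_frames_est = approx_len / (velocity / frame_rate)
    n_dense = int(max(20_000, 25 * n_frames_est))
    phi_dense = np.linspace(phi0, phi1, n_dense)
    lam_dense = turn_rate * phi_dense
    centers_dense = r_cam * _surface_direction(phi_dense, lam_dense)

    phi = _resample_by_arclength(
        phi_dense, centers_dense, velocity / frame_rate
    )
    lam = turn_rate * phi
    poses = _poses_from_angles(
        phi, lam, sphere_radius, imaging_distance, frame_rate
    )
    return Trajectory(
        poses,
        kind="spiral",
        spacing_cm=spacing,
        imaging_distance_cm=imaging_distance,
        velocity_cm_s=velocity,
        frame_rate_hz=frame_rate,
    )


def make_sine_trajectory(
    sphere_radius: float,
    spacing: float,
    imaging_distance: float,
    velocity: float,
    frame_rate: float,
    polar_range: tuple[float, float] = DEFAULT_POLAR_RANGE,
) -> Trajectory:
    """Sine scan: alternating meridian sweeps with an azimuth step between.

    The azimuth step is ``spacing / R`` so adjacent sweeps are ``spacing``
    apart at the equator; ``ceil(2 pi R / spacing)`` sweeps cover 360
    degrees.  Sweeps alternate polar direction (down, up, down, ...) and
    are joined by short polar-cap azimuth transitions.
    """
    _validate_scan_args(sphere_radius, spacing, imaging_distance, velocity, frame_rate)
    phi0, phi1 = polar_range
    if not 0.0 <= phi0 < phi1 <= np.pi:
        raise ValueError("polar_range must satisfy 0 <= lo < hi <= pi")
    dlam = spacing / sphere_radius
    n_sweeps = math.ceil(2.0 * np.pi * sphere_radius / spacing)

    # piecewise path in (phi, lambda): sweep k at lambda = k * dlam
    per_sweep = 400
    per_join = 40
    phi_parts: list[np.ndarray] = []
    lam_parts: list[np.ndarray] = []
    for k in range(n_sweeps):
        down = k % 2 == 0
        sweep_phi = np.linspace(phi0, phi1, per_sweep) if down else np.linspace(
            phi1, phi0, per_sweep
        )
        phi_parts.append(sweep_phi)
        lam_parts.append(np.full(per_sweep, k * dlam))
        if k < n_sweeps - 1:
            end_phi = phi1 if down else phi0
            phi_parts.append(np.full(per_join, end_phi)[1:])
            lam_parts.append(
                np.linspace(k * dlam, (k + 1) * dlam, per_join)[1:]
            )
    phi_dense = np.concatenate(phi_parts)
    lam_dense = np.concatenate(lam_parts)
    u_dense = np.arange(len(phi_dense), dtype=np.float64)

    r_cam = sphere_radius - imaging_distance
    centers_dense = r_cam * _surface_direction(phi_dense, lam_dense)
    u = _resample_by_arclength(u_dense, centers_dense, velocity / frame_rate)
    phi = np.interp(u, u_dense, phi_dense)
    lam = np.interp(u, u_dense, lam_dense)
    poses = _poses_from_angles(
        phi, lam, sphere_radius, imaging_distance, frame_rate
    )
    traj = Trajectory(
        poses,
        kind="sine",
        spacing_cm=spacing,
        imaging_distance_cm=imaging_distance,
        velocity_cm_s=velocity,
        frame_rate_hz=frame_rate,
    )
    traj.n_sweeps = n_sweeps  # type: ignore[attr-defined]
    return traj


def make_custom_trajectory(
    control_points: np.ndarray,
    sphere_center: np.ndarray,
    velocity: float,
    frame_rate: float,
    smoothing: float = 0.0,
) -> Trajectory:
    """Spline-interpolated free path; the camera looks away from ``sphere_center``.

    Stands in for hand-drawn trajectory curves: the control polyline is
    fit with a cubic B-spline, resampled by arc length, and each pose
    looks radially outward (toward the lumen wall) with the up axis
    taken from the local path tangent projected off the view axis.
    """
    from scipy import interpolate

    pts = np.asarray(control_points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("need at least 4 control points for a cubic spline")
    tck, _ = interpolate.splprep(pts.T, s=smoothing)
    u_dense = np.linspace(0.0, 1.0, 20_000)
    dense = np.stack(interpolate.splev(u_dense, tck), axis=1)
    u = _resample_by_arclength(u_dense, dense, velocity / frame_rate)
    c = np.stack(interpolate.splev(u, tck), axis=1)
    tang = np.stack(interpolate.splev(u, tck, der=1), axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    z = c - np.asarray(sphere_center, dtype=np.float64)
    nz = np.linalg.norm(z, axis=1, keepdims=True)
    if (nz < 1e-12).any():
        raise ValueError("control point coincides with sphere_center")
    z /= nz
    y = tang - (tang * z).sum(axis=1, keepdims=True) * z
    ny = np.linalg.norm(y, axis=1, keepdims=True)
    # fall back to an arbitrary perpendicular where the path is radial
    bad = (ny < 1e-9).ravel()
    if bad.any():
        alt = np.cross(z[bad], np.array([0.0, 0.0, 1.0]))
        alt_n = np.linalg.norm(alt, axis=1, keepdims=True)
        alt_n[alt_n < 1e-9] = 1.0
        y[bad] = alt / alt_n
        ny[bad] = 1.0
    y /= ny
    x = np.cross(y, z)
    poses = []
    for k in range(len(u)):
        T = np.eye(4)
        T[:3, 0], T[:3, 1], T[:3, 2], T[:3, 3] = x[k], y[k], z[k], c[k]
        poses.append(CameraPose(T, frame_index=k, timestamp_s=k / frame_rate))
    return Trajectory(
        poses, kind="custom", velocity_cm_s=velocity, frame_rate_hz=frame_rate
    )


# ---------------------------------------------------------------------------
# jitter


def _smooth_columns(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 0 with edge-shrinking window."""
    kernel = np.ones(window) / window
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        padded = np.pad(x[:, j], window // 2, mode="edge")
        out[:, j] = np.convolve(padded, kernel, mode="valid")[: len(x)]
    return out


def add_jitter(
    traj: Trajectory,
    position_amp: float,
    rotation_amp_deg: float,
    seed: int = 0,
) -> Trajectory:
    """Simulate imperfect human scope handling.

    Camera centers receive temporally smoothed (moving average, window 5)
    Gaussian offsets rescaled to an RMS displacement of ``position_amp``
    cm; orientations receive small random rotations with RMS angle
    ``rotation_amp_deg``.  Amplitude 0 leaves poses untouched.
    """
    if position_amp < 0 or rotation_amp_deg < 0:
        raise ValueError("jitter amplitudes must be non-negative")
    n = len(traj)
    rng = np.random.default_rng(seed)
    offsets = np.zeros((n, 3))
    if position_amp > 0 and n > 0:
        raw = rng.normal(size=(n, 3))
        smooth = _smooth_columns(raw, _JITTER_SMOOTH_WINDOW)
        rms = np.sqrt((smooth**2).sum(axis=1).mean())
        offsets = smooth * (position_amp / rms)
    rotvecs = np.zeros((n, 3))
    if rotation_amp_deg > 0 and n > 0:
        raw = rng.normal(size=(n, 3))
        rms_angle = np.sqrt((raw**2).sum(axis=1).mean())
        rotvecs = raw * (np.radians(rotation_amp_deg) / rms_angle)

    poses = []
    for k, p in enumerate(traj.poses):
        T = p.T.copy()
        if rotation_amp_deg > 0:
            T[:3, :3] = Rotation.from_rotvec(rotvecs[k]).as_matrix() @ T[:3, :3]
        T[:3, 3] = T[:3, 3] + offsets[k]
        poses.append(CameraPose(T, p.frame_index, p.timestamp_s))
    return Trajectory(
        poses,
        kind=traj.kind,
        spacing_cm=traj.spacing_cm,
        imaging_distance_cm=traj.imaging_distance_cm,
        velocity_cm_s=traj.velocity_cm_s,
        frame_rate_hz=traj.frame_rate_hz,
    )
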