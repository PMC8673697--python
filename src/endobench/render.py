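"""Ray-cast pinhole renderer for the textured phantom interior.

One primary ray per pixel (no anti-aliasing, for determinism) is cast
from the camera center through the pixel center.  The nearest surface
hit is shaded with an endoscope-like point light co-located with the
camera (configurable offset)::

    L = exposure * albedo * I0 * max(0, cos theta) / r^2

with ``theta`` the angle between the surface normal and the direction
to the light and ``r`` the hit-to-light distance, then clamped to
[0, 1] and quantized to 8 bits.  The albedo is a bilinear sample of the
texture at the barycentric-interpolated UV (the U coordinate wraps).

Meshes tagged as exact spheres take an analytic ray-sphere fast path;
general meshes go through vectorized Moller-Trumbore intersection,
which is adequate below ~20k triangles.  Lens distortion, depth of
focus, sensor noise and motion blur are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endobench.deformation import DeformationProfile, apply_deformation
from endobench.geometry import TriMesh
from endobench.texture import TextureImage
from endobench.trajectory import CameraIntrinsics, CameraPose, Trajectory

_RAY_CHUNK = 2048
_TRI_RAY_CHUNK = 128


@dataclass
class RenderSettings:
    """Camera intrinsics plus illumination and exposure controls.

    ``light_intensity`` is a radiometric scale in cm^2 (an intensity of
    ``r**2`` yields unit radiance at normal incidence at distance r);
    ``light_offset`` displaces the point light from the camera center,
    expressed in the camera frame.
    """

    intrinsics: CameraIntrinsics
    light_intensity: float = 9.0
    light_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    exposure: float = 1.0
    background_color: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.light_offset = np.asarray(self.light_offset, dtype=np.float64).reshape(3)
        if self.light_intensity <= 0:
            raise ValueError("light_intensity must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")


@dataclass
class Frame:
    """One rendered video frame."""

    image: np.ndarray
    frame_index: int
    timestamp_s: float


# ---------------------------------------------------------------------------
# sampling helpers


def _bilinear_sample(tex: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear texture lookup; u wraps (azimuth seam), v clamps (poles)."""
    h, w = tex.shape[:2]
    x = u * w - 0.5
    y = v * h - 0.5
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = (x - x0)[:, None]
    fy = (y - y0)[:, None]
    x0m, x1m = x0 % w, (x0 + 1) % w
    y0m = np.clip(y0, 0, h - 1)
    y1m = np.clip(y0 + 1, 0, h - 1)
    c00 = tex[y0m, x0m].astype(np.float64)
    c01 = tex[y0m, x1m].astype(np.float64)
    c10 = tex[y1m, x0m].astype(np.float64)
    c11 = tex[y1m, x1m].astype(np.float64)
    top = c00 * (1 - fx) + c01 * fx
    bot = c10 * (1 - fx) + c11 * fx
    return (top * (1 - fy) + bot * fy) / 255.0


def _pixel_rays(intr: CameraIntrinsics, pose: CameraPose) -> tuple[np.ndarray, np.ndarray]:
    """World-space origins (3,) and unit directions (H*W, 3), row-major."""
    cx, cy = intr.principal_point
    f = intr.focal_px
    xs = (np.arange(intr.width_px) + 0.5 - cx) / f
    ys = (np.arange(intr.height_px) + 0.5 - cy) / f
    gx, gy = np.meshgrid(xs, ys)
    d_cam = np.stack([gx.ravel(), gy.ravel(), np.ones(gx.size)], axis=1)
    d_cam /= np.linalg.norm(d_cam, axis=1, keepdims=True)
    d_world = d_cam @ pose.R.T
    return pose.t, d_world


# ---------------------------------------------------------------------------
# intersection


def _intersect_sphere(
    origin: np.ndarray, dirs: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest positive ray-sphere hit from inside an origin-centered sphere.

    Returns (hit mask, distances); for an interior origin the positive
    root always exists.
    """
    b = dirs @ origin
    c = origin @ origin - radius * radius
    disc = b * b - c
    hit = disc >= 0
    t = np.full(len(dirs), np.inf)
    sq = np.sqrt(np.maximum(disc, 0.0))
    t_far = -b + sq
    t_near = -b - sq
    t_best = np.where(t_near > 1e-12, t_near, t_far)
    valid = hit & (t_best > 1e-12)
    t[valid] = t_best[valid]
    return valid, t


def _intersect_mesh(
    origin: np.ndarray, dirs: np.ndarray, mesh: TriMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-hit Moller-Trumbore over all faces, chunked over rays.

    Returns (hit mask, distance, face index, bary b1, bary b2).
    """
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    n = len(dirs)
    t_out = np.full(n, np.inf)
    face_out = np.full(n, -1, dtype=np.int64)
    b1_out = np.zeros(n)
    b2_out = np.zeros(n)
    tvec = origin - v0  # (m, 3), shared by every ray
    qvec = np.cross(tvec, e1)  # (m, 3), also ray-independent
    t_num = np.einsum("mk,mk->m", e2, qvec)
    for s in range(0, n, _TRI_RAY_CHUNK):
        d = dirs[s : s + _TRI_RAY_CHUNK]  # (c, 3)
        pvec = np.cross(d[:, None, :], e2[None, :, :])  # (c, m, 3)
        det = np.einsum("mk,cmk->cm", e1, pvec)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = 1.0 / det
            b1 = np.einsum("mk,cmk->cm", tvec, pvec) * inv_det
            b2 = np.einsum("ck,mk->cm", d, qvec) * inv_det
            t = t_num[None, :] * inv_det
        ok = (
            (np.abs(det) > 1e-14)
            & (b1 >= -1e-12)
            & (b2 >= -1e-12)
            & (b1 + b2 <= 1.0 + 1e-12)
            & (t > 1e-9)
        )
        t = np.where(ok, t, np.inf)
        best = np.argmin(t, axis=1)
        rows = np.arange(len(d))
        tb = t[rows, best]
        has = np.isfinite(tb)
        idx = s + rows[has]
        t_out[idx] = tb[has]
        face_out[idx] = best[has]
        b1_out[idx] = b1[rows, best][has]
        b2_out[idx] = b2[rows, best][has]
    return face_out >= 0, t_out, face_out, b1_out, b2_out


def _wrap_interp_uv(
    uv: np.ndarray, faces: np.ndarray, face_idx: np.ndarray,
    b1: np.ndarray, b2: np.ndarray, seam_wrap: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric UV interpolation, optionally seam-aware in U.

    For meshes with a periodic U (``seam_wrap``), a triangle whose U
    spread exceeds 0.5 straddles the equirectangular seam: its low-U
    corners are shifted by +1 before interpolation and the result is
    wrapped back into [0, 1).  Non-periodic meshes interpolate as-is.
    """
    tri_uv = uv[faces[face_idx]]  # (n, 3, 2)
    us = tri_uv[:, :, 0].copy()
    if seam_wrap:
        spread = us.max(axis=1) - us.min(axis=1)
        seam = spread > 0.5
        if seam.any():
            u_seam = us[seam]
            u_seam[u_seam < 0.5] += 1.0
            us[seam] = u_seam
    b0 = 1.0 - b1 - b2
    u = b0 * us[:, 0] + b1 * us[:, 1] + b2 * us[:, 2]
    if seam_wrap:
        u = u % 1.0
    v = b0 * tri_uv[:, 0, 1] + b1 * tri_uv[:, 1, 1] + b2 * tri_uv[:, 2, 1]
    return np.clip(u, 0.0, 1.0), np.clip(v, 0.0, 1.0)


# ---------------------------------------------------------------------------
# rendering


def render_frame_linear(
    mesh: TriMesh,
    texture: TextureImage,
    pose: CameraPose,
    settings: RenderSettings,
) -> np.ndarray:
    """Linear (pre-clamp, pre-quantization) radiance image, (H, W, 3) float."""
    if mesh.sphere_radius is None and mesh.uv is None:
        raise ValueError("mesh has no UV coordinates; cannot texture it")
    intr = settings.intrinsics
    origin, dirs = _pixel_rays(intr, pose)
    n = len(dirs)
    light_pos = pose.t + pose.R @ settings.light_offset

    albedo = np.zeros((n, 3))
    normals = np.zeros((n, 3))
    points = np.zeros((n, 3))
    if mesh.sphere_radius is not None:
        hit, t = _intersect_sphere(origin, dirs, mesh.sphere_radius)
        points[hit] = origin + t[hit, None] * dirs[hit]
        # interior surface normal points back toward the lumen center
        normals[hit] = -points[hit] / mesh.sphere_radius
        from endobench.geometry import spherical_uv

        uv = spherical_uv(points[hit], mesh.sphere_radius)
        albedo[hit] = _bilinear_sample(texture.pixels, uv[:, 0], uv[:, 1])
    else:
        hit, t, fidx, b1, b2 = _intersect_mesh(origin, dirs, mesh)
        points[hit] = origin + t[hit, None] * dirs[hit]
        v0 = mesh.vertices[mesh.faces[fidx[hit], 0]]
        e1 = mesh.vertices[mesh.faces[fidx[hit], 1]] - v0
        e2 = mesh.vertices[mesh.faces[fidx[hit], 2]] - v0
        fn = np.cross(e1, e2)
        fn /= np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), 1e-300)
        # orient toward the viewer
        flip = np.einsum("ij,ij->i", fn, dirs[hit]) > 0
        fn[flip] = -fn[flip]
        normals[hit] = fn
        u, v = _wrap_interp_uv(
            mesh.uv, mesh.faces, fidx[hit], b1[hit], b2[hit], mesh.uv_seam_wrap
        )
        albedo[hit] = _bilinear_sample(texture.pixels, u, v)

    out = np.zeros((n, 3))
    if hit.any():
        to_light = light_pos - points[hit]
        r = np.linalg.norm(to_light, axis=1)
        r = np.maximum(r, 1e-12)
        cos_th = np.einsum("ij,ij->i", normals[hit], to_light / r[:, None])
        cos_th = np.maximum(cos_th, 0.0)
        shade = settings.exposure * settings.light_intensity * cos_th / (r * r)
        out[hit] = albedo[hit] * shade[:, None]
    bg = np.asarray(settings.background_color, dtype=np.float64) / 255.0
    out[~hit] = bg
    return out.reshape(intr.height_px, intr.width_px, 3)


def render_frame(
    mesh: TriMesh,
    texture: TextureImage,
    pose: CameraPose,
    settings: RenderSettings,
) -> Frame:
    """Render one 8-bit frame (see module docstring for the shading model)."""
    linear = render_frame_linear(mesh, texture, pose, settings)
    img = np.floor(np.clip(linear, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return Frame(img, pose.frame_index, pose.timestamp_s)


def render_video(
    mesh_rest: TriMesh,
    profile: DeformationProfile | None,
    level: float,
    texture: TextureImage,
    trajectory: Trajectory,
    settings: RenderSettings,
) -> list[Frame]:
    """One frame per trajectory pose, deforming the mesh at each timestamp."""
    frames = []
    for pose in trajectory.poses:
        if profile is not None and level > 0.0:
            mesh = apply_deformation(mesh_rest, profile, level, pose.timestamp_s)
        else:
            mesh = mesh_rest
        frame = render_frame(mesh, texture, pose, settings)
        frame.frame_index = pose.frame_index
        frame.timestamp_s = pose.timestamp_s
        frames.append(frame)
    return frames
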