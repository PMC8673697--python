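"""Triangle-mesh phantoms and point clouds.

The phantom is the virtual stand-in for the hollow organ being scanned
(here, a distended bladder modelled as a 10 cm sphere).  Meshes carry
per-vertex UV coordinates so a texture can be wrapped onto the inner
surface; point clouds are the common currency of the shape metrics.

All coordinates are in centimeters unless a model has been normalized
(see :func:`endobench.shape_metrics.normalize_model`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _trimesh


class MeshFormatError(ValueError):
    """Raised for unreadable or non-triangular mesh files."""


@dataclass
class TriMesh:
    """Triangle mesh with optional per-vertex UV texture coordinates.

    Attributes
    ----------
    vertices : (n, 3) float array, cm
    faces : (m, 3) int array of vertex indices
    uv : (n, 2) float array in [0, 1]^2, or None
    sphere_radius : float or None
        Set when the mesh is an exact sphere centered at the origin;
        enables the renderer's analytic ray-sphere fast path.
    uv_seam_wrap : bool
        True when the U coordinate is periodic (equirectangular
        mapping); tells the renderer to interpolate U across the seam.
    """

    vertices: np.ndarray
    faces: np.ndarray
    uv: np.ndarray | None = None
    sphere_radius: float | None = None
    uv_seam_wrap: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.uv is not None:
            self.uv = np.asarray(self.uv, dtype=np.float64).reshape(-1, 2)
            if len(self.uv) != len(self.vertices):
                raise ValueError("uv must be per-vertex")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces) and (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValueError("degenerate face with repeated vertex indices")

    # -- derived quantities -------------------------------------------------

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned bounding box [min; max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        return self.bounds[1] - self.bounds[0]

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (trimesh convention)."""
        return np.asarray(self.as_trimesh().vertex_normals, dtype=np.float64)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.uv is None else self.uv.copy(),
            self.sphere_radius,
            self.uv_seam_wrap,
        )

    def as_trimesh(self) -> _trimesh.Trimesh:
        m = _trimesh.Trimesh(self.vertices, self.faces, process=False)
        if self.uv is not None:
            m.visual = _trimesh.visual.TextureVisuals(uv=self.uv)
        return m


@dataclass
class PointCloud:
    """Bag of 3D points, in cm or unitless after bounding-box normalization."""

    points: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) and not np.isfinite(self.points).all():
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "PointCloud":
        return PointCloud(self.points.copy(), self.normalized)


# ---------------------------------------------------------------------------
# construction


def spherical_uv(points: np.ndarray, radius: float) -> np.ndarray:
    """Equirectangular UV for points on an origin-centered sphere.

    u = (atan2(y, x) + pi) / 2pi, v = acos(z / r) / pi.
    """
    p = np.asarray(points, dtype=np.float64)
    u = (np.arctan2(p[:, 1], p[:, 0]) + np.pi) / (2.0 * np.pi)
    v = np.arccos(np.clip(p[:, 2] / radius, -1.0, 1.0)) / np.pi
    return np.column_stack([u, v])


def make_sphere_phantom(diameter: float, subdivisions: int = 4) -> TriMesh:
    """Watertight icosphere phantom centered at the origin.

    The default 10 cm diameter mimics a distended bladder.  An icosphere
    (subdivided icosahedron, vertices re-projected onto the sphere) is
    used rather than a latitude/longitude sphere because its triangles
    are near-uniform in area.  UVs are the equirectangular mapping.

    Parameters
    ----------
    diameter : float, cm
    subdivisions : int, >= 1
        Each level quadruples the face count (level 4: 5120 faces).
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    if subdivisions < 1:
        raise ValueError(f"subdivisions must be >= 1, got {subdivisions}")
    r = diameter / 2.0
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    faces = np.asarray(ico.faces, dtype=np.int64)
    return TriMesh(
        verts, faces, uv=spherical_uv(verts, r), sphere_radius=r,
        uv_seam_wrap=True,
    )


# ---------------------------------------------------------------------------
# IO (OBJ with vt records, ascii/binary PLY) via trimesh


def save_mesh(mesh: TriMesh, path: str | Path) -> Path:
    """Write OBJ (with vt texture coordinates) or PLY, by extension.

    OBJ is written at 17 significant digits so coordinates and UVs
    round-trip float64 exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".obj":
        lines = ["# endobench mesh"]
        for v in mesh.vertices:
            lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        if mesh.uv is not None:
            for t in mesh.uv:
                lines.append(f"vt {t[0]:.17g} {t[1]:.17g}")
            for f in mesh.faces + 1:
                lines.append(f"f {f[0]}/{f[0]} {f[1]}/{f[1]} {f[2]}/{f[2]}")
        else:
            for f in mesh.faces + 1:
                lines.append(f"f {f[0]} {f[1]} {f[2]}")
        path.write_text("\n".join(lines) + "\n")
    else:
        mesh.as_trimesh().export(path)
    return path


def load_mesh(path: str | Path) -> TriMesh:
    """Load an OBJ/PLY triangle mesh; UVs populated when present.

    Raises
    ------
    MeshFormatError
        For unreadable files, non-triangular faces, or a PLY that holds
        only points (use :func:`load_pointcloud` for those).
    """
    path = Path(path)
    if not path.is_file():
        raise MeshFormatError(f"cannot read mesh file: {path}")
    try:
        loaded = _trimesh.load(path, process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises assorted types
        raise MeshFormatError(f"failed to parse {path}: {exc}") from exc
    if isinstance(loaded, _trimesh.PointCloud) or not len(
        getattr(loaded, "faces", [])
    ):
        raise MeshFormatError(
            f"{path} contains no faces; load it with load_pointcloud() instead"
        )
    if loaded.faces.shape[1] != 3:
        raise MeshFormatError(f"{path} has non-triangular faces")
    uv = None
    visual = getattr(loaded, "visual", None)
    if visual is not None and getattr(visual, "uv", None) is not None:
        uv = np.asarray(visual.uv, dtype=np.float64)
        if len(uv) != len(loaded.vertices):
            uv = None
    return TriMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces), uv=uv)


def save_pointcloud(cloud: PointCloud, path: str | Path) -> Path:
    """Write a point cloud as PLY."""
    path = Path(path)
    _trimesh.PointCloud(cloud.points).export(path)
    return path


def load_pointcloud(path: str | Path) -> PointCloud:
    """Read a PLY/OBJ point cloud (faces, if any, are ignored)."""
    path = Path(path)
    if not path.is_file():
        raise MeshFormatError(f"cannot read point cloud file: {path}")
    try:
        loaded = _trimesh.load(path, process=False)
    except Exception as exc:
        raise MeshFormatError(f"failed to parse {path}: {exc}") from exc
    pts = np.asarray(loaded.vertices, dtype=np.float64)
    if len(pts) == 0:
        raise MeshFormatError(f"{path} contains no points")
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# sampling


def sample_mesh_to_pointcloud(mesh: TriMesh, n: int, seed: int = 0) -> PointCloud:
    """Area-weighted Monte-Carlo surface sampling.

    Triangles are chosen with probability proportional to their area and
    the point is uniform in barycentric coordinates, so the expected
    point density is uniform over the surface.  Deterministic for a
    fixed ``(mesh, n, seed)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(mesh.faces) == 0:
        raise ValueError("cannot sample an empty mesh")
    rng = np.random.default_rng(seed)
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    tri = rng.choice(len(areas), size=n, p=areas / total)
    # uniform barycentric via square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a = mesh.vertices[mesh.faces[tri, 0]]
    b = mesh.vertices[mesh.faces[tri, 1]]
    c = mesh.vertices[mesh.faces[tri, 2]]
    pts = (1.0 - r1)[:, None] * a + (r1 * (1.0 - r2))[:, None] * b + (
        r1 * r2
    )[:, None] * c
    return PointCloud(pts)
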