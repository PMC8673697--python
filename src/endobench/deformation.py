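"""Time-periodic tissue deformation of the phantom mesh.

Deformation emulates breathing, heartbeat or intentional compression:
a selected patch of vertices moves from its rest position out to a
maximum displacement and back, once per cycle.  A *profile* fixes which
vertices move, their per-vertex weights and directions, the maximum
displacement ``D_max`` (cm) and the cycle frequency ``f_d`` (Hz); the
*level* ``L`` in [0, 1] scales the realized displacement relative to the
profile's maximum, so ``L = 0`` is no deformation and ``L = 1`` reaches
``D_max``.

Displaced position at time ``t``::

    x_v(t) = rest_v + L * D_max * w_v * 0.5 * (1 - cos(2 pi f_d t)) * dir_v

The raised-cosine waveform is a smooth out-and-back motion; a triangular
waveform is available for configs that want a constant-speed excursion.
The phase is computed from ``(f_d * t) mod 1`` so the cycle is exactly
periodic in floating point whenever ``f_d * t`` is exact (e.g. one
0.2 Hz cycle takes exactly five seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from endobench.geometry import TriMesh


@dataclass
class DeformationProfile:
    """Which vertices move, how far, in which direction, and how fast."""

    vertex_ids: np.ndarray
    weights: np.ndarray
    directions: np.ndarray
    max_displacement: float
    frequency: float
    waveform: str = "raised_cosine"

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64).ravel()
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        self.directions = np.asarray(self.directions, dtype=np.float64).reshape(
            -1, 3
        )
        if not (len(self.vertex_ids) == len(self.weights) == len(self.directions)):
            raise ValueError("vertex_ids, weights, directions must align")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        norms = np.linalg.norm(self.directions, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.waveform not in ("raised_cosine", "triangular"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    # -- YAML (de)serialization --------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "vertex_ids": self.vertex_ids.tolist(),
            "weights": self.weights.tolist(),
            "directions": self.directions.tolist(),
            "max_displacement": float(self.max_displacement),
            "frequency": float(self.frequency),
            "waveform": self.waveform,
        }
        path.write_text(yaml.safe_dump(payload))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeformationProfile":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            np.asarray(payload["vertex_ids"]),
            np.asarray(payload["weights"]),
            np.asarray(payload["directions"]),
            payload["max_displacement"],
            payload["frequency"],
            payload.get("waveform", "raised_cosine"),
        )


def make_radial_profile(
    mesh: TriMesh,
    center_vertex: int,
    radius: float,
    max_displacement: float,
    frequency: float,
    waveform: str = "raised_cosine",
) -> DeformationProfile:
    """Cosine-falloff patch around ``center_vertex``.

    Vertices within Euclidean distance ``radius`` of the center vertex
    (a geodesic surrogate on smooth meshes) are selected with weight
    ``w_v = 0.5 * (1 + cos(pi * dist_v / radius))`` — 1 at the center,
    0 at the rim.  Displacement directions default to the inward rest
    normals, giving a lumen-ward bulge.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= center_vertex < len(mesh.vertices):
        raise ValueError(f"center_vertex {center_vertex} out of range")
    d = np.linalg.norm(mesh.vertices - mesh.vertices[center_vertex], axis=1)
    ids = np.flatnonzero(d <= radius)
    if len(ids) == 0:
        raise ValueError("no vertices within radius of the center vertex")
    weights = 0.5 * (1.0 + np.cos(np.pi * d[ids] / radius))
    directions = -mesh.vertex_normals()[ids]  # inward at rest
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    return DeformationProfile(
        ids, weights, directions, max_displacement, frequency, waveform
    )


def _waveform_value(profile: DeformationProfile, t: float) -> float:
    """Excursion in [0, 1]; exactly 0 at integer multiples of the period."""
    phase = math.fmod(profile.frequency * t, 1.0)  # cycle fraction
    if profile.waveform == "triangular":
        return 1.0 - abs(2.0 * phase - 1.0)
    return 0.5 * (1.0 - math.cos(2.0 * math.pi * phase))


def apply_deformation(
    mesh: TriMesh, profile: DeformationProfile, level: float, t: float
) -> TriMesh:
    """Deformed copy of ``mesh`` at time ``t`` and deformation level ``level``.

    Displacement is linear in ``level`` and never exceeds
    ``level * D_max`` anywhere.  The input mesh is not mutated; rest
    normals stored in the profile are used throughout the cycle.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"deformation level must be in [0, 1], got {level}")
    out = mesh.copy()
    if level == 0.0 or profile.max_displacement == 0.0:
        return out
    amp = level * profile.max_displacement * _waveform_value(profile, t)
    if amp == 0.0:
        return out  # bit-identical to rest at every whole cycle
    out.vertices[profile.vertex_ids] = (
        out.vertices[profile.vertex_ids]
        + (amp * profile.weights)[:, None] * profile.directions
    )
    out.sphere_radius = None  # no longer an exact sphere
    return out
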