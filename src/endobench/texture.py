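"""Procedural textures for the phantom's inner surface.

Two texture families are generated:

* a *vascularized* mucosa-like texture — branching, curving, tapering
  vessel strokes drawn over a smooth pinkish base — which gives feature
  points for the reconstruction pipeline under test;
* a *multi-precision grid* texture (black grid lines at a fine and a
  coarse pitch, white alphanumeric cell labels, blue background) wrapped
  onto the auxiliary model so texture-mapping quality can be judged by
  eye against known coordinates.

Vessels are drawn by a persistent random walk: each stroke starts at a
random point with a random heading, steps 2 px at a time while the
heading receives Gaussian curvature noise, spawns side branches with a
fixed per-step probability, and its stamped disk radius tapers linearly
from a random start width down to 1 px.  Drawing stops as soon as the
binary vessel mask reaches the requested coverage (or a stroke-count
cap).  All randomness flows through one ``numpy`` generator, so results
are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from endobench import _font

_STEP_PX = 2.0          # walk step length
_HEADING_SIGMA = 0.2    # rad, curvature noise per step
_BRANCH_PROB = 0.15     # per-step branch probability
_VESSEL_CAP = 10_000    # safety cap on stroke count
_LABEL_MARGIN = 4       # px between coarse grid line and label


@dataclass
class TextureImage:
    """RGB 8-bit raster wrapped onto the phantom (row-major, H x W x 3)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.height < 16 or self.width < 16:
            raise ValueError("texture must be at least 16 x 16 px")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "TextureImage":
        return TextureImage(self.pixels.copy())

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        iio.imwrite(path, self.pixels)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TextureImage":
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        return cls(arr[:, :, :3])


@dataclass
class VascularParams:
    """Controls for the vessel-drawing random walk.

    ``coverage`` is the target fraction of texture pixels covered by the
    binary vessel mask; drawing stops once it is reached.
    """

    max_width: int = 8
    max_length: int = 220
    coverage: float = 0.25
    vessel_color: tuple[int, int, int] = (150, 40, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        self.vessel_color = tuple(self.vessel_color)
        if self.max_width < 1:
            raise ValueError("max_width must be >= 1 px")
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2 px")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class GridParams:
    """Controls for the auxiliary multi-precision grid texture."""

    coarse_pitch: int = 64
    fine_pitch: int = 16
    line_color: tuple[int, int, int] = (0, 0, 0)
    label_color: tuple[int, int, int] = (255, 255, 255)
    background_color: tuple[int, int, int] = (20, 60, 200)
    charset: str = _font.CHARSET

    def __post_init__(self) -> None:
        self.line_color = tuple(self.line_color)
        self.label_color = tuple(self.label_color)
        self.background_color = tuple(self.background_color)
        if self.fine_pitch < 8 or self.coarse_pitch < 8:
            raise ValueError("grid pitches must be >= 8 px")
        if self.coarse_pitch % self.fine_pitch != 0:
            raise ValueError("fine_pitch must divide coarse_pitch")


# ---------------------------------------------------------------------------
# vascular texture


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> int:
    """Set a filled disk in ``mask``; return the number of newly set pixels."""
    h, w = mask.shape
    r = max(radius, 0.5)
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    y0, y1 = max(y0, 0), min(y1, h)
    x0, x1 = max(x0, 0), min(x1, w)
    if y0 >= y1 or x0 >= x1:
        return 0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    patch = mask[y0:y1, x0:x1]
    added = int(np.count_nonzero(disk & ~patch))
    patch |= disk
    return added


def synthesize_vascular_texture(
    base: TextureImage, params: VascularParams
) -> tuple[TextureImage, np.ndarray]:
    """Draw tapering, branching vessel strokes over ``base``.

    Returns the composited image and the boolean vessel mask.  Strokes
    are added until the mask covers ``params.coverage`` of the pixels
    (checked after every stamped disk, so overshoot is at most one disk)
    or a stroke-count cap is hit.

    The per-stroke random draws (start, heading, width fraction, per-step
    curvature and branch decisions) do not depend on ``max_width``, so
    enlarging ``max_width`` only dilates the same stroke skeletons.
    """
    if params.coverage > 0.95:
        raise ValueError(
            "coverage > 0.95 is unreachable with vessel strokes; use a solid fill"
        )
    h, w = base.height, base.width
    mask = np.zeros((h, w), dtype=bool)
    out = base.copy()
    if params.coverage == 0.0:
        return out, mask

    rng = np.random.default_rng(params.seed)
    target = params.coverage * h * w
    covered = 0
    n_steps = max(int(params.max_length / _STEP_PX), 1)

    vessels = 0
    done = False
    while covered < target and vessels < _VESSEL_CAP and not done:
        vessels += 1
        cy, cx = rng.random() * h, rng.random() * w
        heading = rng.random() * 2.0 * np.pi
        # width fraction drawn once so widths scale monotonically in max_width
        w0 = 1.0 + rng.random() * (params.max_width - 1.0)
        # stack of (y, x, heading, width, steps_left); branches inherit a
        # tapered width from their parent at the branch point
        stack = [(cy, cx, heading, w0, n_steps)]
        while stack and not done:
            y, x, hd, wid, left = stack.pop()
            while left > 0:
                frac = left / n_steps
                radius = 0.5 * max(1.0, 1.0 + (wid - 1.0) * frac)
                covered += _stamp_disk(mask, y, x, radius)
                if covered >= target:
                    done = True
                    break
                hd += rng.normal(0.0, _HEADING_SIGMA)
                y += _STEP_PX * np.sin(hd)
                x += _STEP_PX * np.cos(hd)
                left -= 1
                if not (0 <= y < h and 0 <= x < w):
                    break
                branch_u = rng.random()
                side = rng.normal(0.0, 1.0)  # drawn unconditionally: fixed stream
                if branch_u < _BRANCH_PROB:
                    off = np.sign(side) * (np.pi / 4 + 0.3 * abs(side))
                    stack.append(
                        (y, x, hd + off, max(1.0, wid * frac * 0.7), left // 2)
                    )
    out.pixels[mask] = np.asarray(params.vessel_color, dtype=np.uint8)
    return out, mask


# ---------------------------------------------------------------------------
# auxiliary grid texture


def _row_letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style)."""
    s = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        s = chr(ord("A") + rem) + s
    return s


def make_auxiliary_grid_texture(
    width: int, height: int, params: GridParams | None = None
) -> TextureImage:
    """Multi-precision coordinate grid on a blue background.

    Black 1 px lines at the fine pitch, 3 px lines at the coarse pitch,
    and a white label (row letter + column number, e.g. ``A1``) in the
    top-left corner of every coarse cell, rendered from the embedded
    5x7 glyph set.
    """
    params = params or GridParams()
    if width % params.fine_pitch or height % params.fine_pitch:
        raise ValueError("width and height must be multiples of fine_pitch")
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(params.background_color, dtype=np.uint8)

    line = np.asarray(params.line_color, dtype=np.uint8)
    fine_rows = np.arange(height) % params.fine_pitch == 0
    fine_cols = np.arange(width) % params.fine_pitch == 0
    img[fine_rows, :] = line
    img[:, fine_cols] = line
    coarse_rows = np.isin(
        np.arange(height) % params.coarse_pitch, (0, 1, params.coarse_pitch - 1)
    )
    coarse_cols = np.isin(
        np.arange(width) % params.coarse_pitch, (0, 1, params.coarse_pitch - 1)
    )
    img[coarse_rows, :] = line
    img[:, coarse_cols] = line

    label_color = np.asarray(params.label_color, dtype=np.uint8)
    n_rows = -(-height // params.coarse_pitch)
    n_cols = -(-width // params.coarse_pitch)
    for ri in range(n_rows):
        for ci in range(n_cols):
            text = f"{_row_letters(ri)}{ci + 1}"
            raster = _font.render_label(text)
            gh, gw = raster.shape
            if (
                gh + 2 * _LABEL_MARGIN > params.coarse_pitch
                or gw + 2 * _LABEL_MARGIN > params.coarse_pitch
            ):
                raise ValueError(
                    f"coarse cell {params.coarse_pitch} px too small for label "
                    f"{text!r} ({gw}x{gh} px plus margins)"
                )
            y0 = ri * params.coarse_pitch + _LABEL_MARGIN
            x0 = ci * params.coarse_pitch + _LABEL_MARGIN
            y1, x1 = min(y0 + gh, height), min(x0 + gw, width)
            sub = raster[: y1 - y0, : x1 - x0]
            img[y0:y1, x0:x1][sub] = label_color
    return TextureImage(img)


# ---------------------------------------------------------------------------
# preset base


def make_preset_base_texture(
    width: int = 512, height: int = 512, seed: int = 0
) -> TextureImage:
    """Smooth low-frequency pinkish field used as the default vessel base.

    Value noise: a coarse random lattice upsampled with cubic
    interpolation, mapped into a pink/red mucosa-like color range.
    """
    if width < 16 or height < 16:
        raise ValueError("texture must be at least 16 x 16 px")
    rng = np.random.default_rng(seed)
    lattice = rng.random((9, 9))
    field_ = ndimage.zoom(lattice, (height / 9, width / 9), order=3)[
        :height, :width
    ]
    field_ = np.clip(field_, 0.0, 1.0)
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:, :, 0] = np.round(175 + 55 * field_)
    img[:, :, 1] = np.round(110 + 40 * field_)
    img[:, :, 2] = np.round(120 + 40 * field_)
    return TextureImage(img)
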