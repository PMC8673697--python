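# Methods

This note documents the models behind `endobench`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
setting does and does not establish about real endoscopy data.

## Scene model

All scene coordinates are centimeters.  The preset phantom is a
watertight icosphere of diameter 10 cm (a distended bladder is roughly
this size), centered at the origin.  An icosphere rather than a
latitude/longitude sphere keeps triangle areas near-uniform, which
matters for area-weighted surface sampling and for rendering without
pole-dense geometry.  Subdivision level 4 (5120 faces, relative area
error ~1.2e-3) is the default; vertices are exactly on the sphere, so
the bounding box equals the nominal diameter to machine precision.

UVs are the equirectangular mapping `u = (atan2(y,x)+pi)/2pi`,
`v = acos(z/r)/pi`.  Rather than duplicating vertices along the
`u = 0/1` seam (which would force some coordinates outside [0,1]),
meshes carry a `uv_seam_wrap` flag and the renderer interpolates U
across the seam for flagged meshes: inside a triangle whose U spread
exceeds 0.5, low-U corners are shifted by +1 before barycentric
interpolation and the result is wrapped back.  Imported meshes default
to non-periodic UVs.

Arbitrary OBJ/PLY meshes can replace the sphere.  OBJ is written at 17
significant digits so geometry and UVs round-trip float64 exactly.

## Textures

**Vascular texture.**  The literature does not pin down a drawing
primitive for mucosal vasculature, so a deliberately simple stochastic
model is used: strokes are persistent random walks (step 2 px, heading
perturbed by Gaussian noise of sigma 0.2 rad per step), with a branch
probability of 0.15 per step, and a stamped disk radius tapering
linearly from a per-stroke random start width (<= `max_width`, default
8 px) down to 1 px.  Strokes accumulate until the binary vessel mask
reaches the requested coverage (default 0.25); the stop condition is
checked after every stamp, so overshoot is bounded by one disk.  This
produces branching, curving, tapering structures with very few
parameters; it makes no claim of biophysical realism.  Note one
consequence of coverage-based stopping: across two runs differing only
in `max_width`, the final mask fractions can differ by up to one stamp
area in either direction, although the underlying stroke skeletons are
identical and the wider mask is a superset at equal stamp counts.

The default base is value noise (a 9x9 random lattice, cubic
upsampled) mapped into a pink/red range — smooth at pixel scale
(lag-1 autocorrelation > 0.9) like defocused mucosa.  Any PNG can be
supplied instead.

**Auxiliary grid.**  Two grid scales: 1 px lines at the fine pitch
(default 16 px) and 3 px lines at the coarse pitch (default 64 px;
the fine pitch must divide it), white spreadsheet-style labels ("A1",
"B3", ...) in each coarse cell, on a blue background.  Labels are
rendered from an embedded 5x7 bitmap font for byte-exact
reproducibility across systems.  "Multi-precision" is realized as
exactly these two scales; both pitches are configurable.

## Trajectories

The camera sits inside the lumen at radius `R - d` (`d` = imaging
distance) and looks radially outward; the per-frame distance from the
camera center to the wall along the optical axis is therefore exactly
`d` by construction.

* **Spiral**: the viewed surface point follows
  `lambda(phi) = 2 pi R phi / spacing`, i.e. one full turn of azimuth
  per `spacing` of polar arc, so neighboring turns are `spacing` apart.
* **Sine**: `ceil(2 pi R / spacing)` alternating meridian sweeps with
  an azimuth step `spacing / R` between them (adjacent sweeps are
  exactly `spacing` apart at the equator — the spacing of this pattern
  is defined equatorially, since meridians converge at the poles),
  joined by short polar-cap transitions.

Frames are sampled by numeric arc-length integration of the camera
path (dense polyline, >= 25 samples per output frame) so consecutive
camera centers are `velocity / frame_rate` apart to well under 1%.
The default polar range [0.05 pi, 0.95 pi] avoids the exact poles,
where the spiral's arc speed degenerates; the full range is
configurable.

Camera convention: right-handed, +Z forward (toward the wall), +Y the
meridian tangent (down the scan), world-from-camera matrices — the
dominant convention of SfM tooling.  Roll is therefore continuous
along the scan.

Jitter emulates imperfect human handling: per-frame Gaussian offsets
smoothed with a 5-frame moving average and rescaled to an exact RMS of
`position_amp`, plus random rotations rescaled to an RMS angle of
`rotation_amp`.  Smoothing makes the perturbation temporally coherent
(hand tremor, not white noise).

## Deformation

A deformation profile selects vertices within a Euclidean radius of a
center vertex (a geodesic surrogate that is accurate on smooth convex
shapes), weights them with a cosine falloff
`w = (1 + cos(pi d / radius)) / 2`, and displaces them along their
inward rest normals:

```
x(t) = rest + L * D_max * w * 0.5*(1 - cos(2 pi f t)) * dir
```

The raised cosine is the simplest smooth out-and-back waveform
consistent with "move out to a maximum and revert"; a triangular
waveform is available.  The level `L` in [0, 1] scales displacement
linearly, so level sweeps are directly comparable.  Rest normals are
used throughout a cycle (no re-computation mid-cycle) for determinism.

The phase is computed as `fmod(f*t, 1)`, which makes the cycle
bit-exactly periodic whenever `f*t` is representable — in particular
the 0.2 Hz default returns the mesh to its rest vertices exactly at
t = 5 s.  For arbitrary real `t`, periodicity holds to the ulp.

## Rendering

One primary ray per pixel through the pixel center (no anti-aliasing,
for determinism).  Meshes tagged as exact spheres use the analytic
ray-sphere intersection and analytic UVs; general (e.g. deformed)
meshes use vectorized Moller-Trumbore intersection, chunked over rays,
which is adequate below ~20k triangles at the default 200x200
resolution.  Shading is Lambertian with a point light at the camera
center (offset configurable):
`L = exposure * albedo * I0 * max(0, cos theta) / r^2`, clamped and
quantized to 8 bits.  `I0` is in cm^2: `I0 = d^2` produces unit
radiance at normal incidence at distance `d`.  Lens distortion, depth
of focus, sensor noise and motion blur are deliberately absent; the
hooks live in `RenderSettings` for forward compatibility.

## Synthesis defaults

Defaults are chosen once as representative cystoscopy settings:
horizontal FOV 110 degrees (wide-angle cystoscope optics), 30 fps,
velocity 1 cm/s, trajectory spacing 0.7 cm, imaging distance 2.5 cm,
200x200 px frames, texture 512x512 px with 25% vascular coverage.
The benchmark groups sweep exactly one variable each: A = {spiral,
sine}; B = spacing {0.2, 0.3, 0.4, 0.7} cm; C = imaging distance
{2.0, 2.5, 3.5, 4.0} cm; D = deformation level {0, 0.2, 0.5, 1.0} at
0.2 Hz (one cycle per five seconds), all on the 10 cm sphere.  The
four group-D levels cover both endpoints and the clinically
interesting low-deformation regime.

A master seed fans out to per-subsystem seeds (texture, jitter,
sampling) through a fixed SeedSequence expansion, so each subsystem is
independently reproducible and a whole run is a pure function of
(config, seed).  The canonical "video" is the lossless PNG frame
directory; an MP4 is written only as a convenience copy when an ffmpeg
backend is available.

## Metrics: numerical choices

**Alignment.**  Monocular reconstruction recovers poses up to a global
similarity, so reconstructed camera centers are aligned to ground
truth with Umeyama's closed-form least-squares similarity before APE
is computed.  The fit uses centers only (not orientations), matching
standard trajectory-evaluation practice; rotations are carried along
as `R_a R_i`.  Degenerate geometry (coincident or collinear centers)
is rejected rather than silently fit.

**APE/RPE.**  Frobenius norms of `(P^rec)^-1 P^gt - I` per frame (APE)
or per relative motion (RPE), aggregated as RMS.  The RPE pair set is
consecutive frames by default — the drift-local choice — with an
all-pairs mode available; the denominator counts pairs.  Translation-
and rotation-only variants operate on the exact factorization
`P = P_t P_r`.  APE/RPE values are unitless matrix norms; translation
entries are in the aligned ground-truth unit.

**SRE/SRC.**  Models are normalized by scaling the longest
bounding-box edge to 1 and centering the box at the origin, then the
reconstruction is registered to the ground truth with point-to-point
ICP (nearest-neighbour correspondences on a k-d tree, closed-form SVD
update; defaults max_iter 50, tol 1e-6, full correspondence set).  SRE
is the RMS nearest-neighbour distance from reconstructed to
ground-truth points; its attainable range in the normalized box is
[0, sqrt(3)].  For SRC both clouds are voxelized at edge 0.04
(normalized units) — binning removes the influence of point density —
and a ground-truth voxel counts as observed when a reconstructed voxel
center lies within 0.01 of its center.  Since the default threshold is
below the edge, observedness degenerates to exact voxel coincidence at
the defaults; both parameters are configurable.  The numerator counts
*distinct* observed ground-truth voxels so SRC cannot exceed 100% even
with generous thresholds; a strict-literal mode (counting observed
reconstructed voxels, identical at the defaults) is provided.

**Partial reconstructions.**  Normalizing a partial model by its own
bounding box inflates its scale relative to the ground truth.  Both
behaviors are exposed: the default normalizes each model by its own
box; `normalize_by_gt_box=True` scales the reconstruction by the
ground-truth box instead and is the right choice for fixtures with
large contiguous dropout.

## Perturbation fixtures

`make_perturbed_fixture` manufactures controlled "reconstructions"
from a ground-truth bundle: isotropic Gaussian noise (sigma in
normalized units), contiguous-cap dropout (the points most extreme
along a random direction — the failure mode of a pipeline that never
saw part of the organ; random per-point dropout would barely move
voxel-based SRC), a global similarity offset, and a single-frame
rotation error chained to all later frames.  These realize the
scenarios the metric suite is designed to tell apart: alignment
removes the similarity exactly; the chained error produces a large APE
with exactly one elevated consecutive-RPE pair.

## What the synthetic setting does not show

Passing this suite demonstrates the *metrics and plumbing* are
correct, and that a pipeline's scores degrade monotonically under
controlled corruption.  It does not establish performance on real
tissue: the renderer omits specular wet-mucosa highlights, fluid and
bubble artifacts, lens distortion, sensor noise and motion blur; the
vascular texture is a stochastic stand-in, not measured vasculature;
deformation is a single smooth bulge, not physiological motion; and
the phantom is convex, unlike a real bladder with trabeculation.
Scores obtained here are upper bounds on real-world behavior.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: short
equatorial scans (tens to hundreds of frames), 32-64 px test frames
(200 px for the geometry checks), 5k-20k point clouds for metric
tests, 10k points for the SRC best case.  All quantities being checked
(counts, bounds, invariances, monotonic trends) are scale-free; the
sizes were picked at the point where their estimates are stable.
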