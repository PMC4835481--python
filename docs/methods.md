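# Methods

## Stain separation

Brightfield stains are modelled as Beer–Lambert absorbers: with background
intensity `i0` (default 255) the optical density of channel *c* is
`OD_c = −log10(max(I_c, 1) / i0)`. The clamp of zero intensities to 1 keeps
OD finite and is the only deviation from the pure model; intensities above
`i0` are treated as zero density. The forward render
(`od_to_rgb`) rounds half away from zero, which matters only at the ±1
intensity level in tests. A stain profile is a 3×3 matrix of unit,
non-negative OD direction vectors; for two-stain material the third row is
the normalized cross product of the first two with components made
non-negative (absolute value), the convention of the classic colour
deconvolution tools. Deconvolution solves `OD = d · M` per pixel and clamps
negative densities to zero.

The shipped profiles for BDA, BDA+Neutral Red, Pha-L, Pha-L+thionine and
BDA+cytochrome oxidase are *plausible placeholders* (DAB-like tracer
vectors, red/blue counterstains): no calibrated vectors for these stain
combinations are published, so quantitative work should acquire
series-specific vectors with `acquire_stain_vectors` (unit-normalized mean
OD of user-marked single-stain regions) or load a profile JSON.

Quantization bounds the achievable inversion accuracy: an 8-bit rounding
error of ±0.5 intensity maps to an OD error of roughly
`0.5·10^OD/(255·ln 10)`, which grows exponentially with density. With the
well-conditioned synthetic calibration profile (condition number ≈ 1.8)
and densities up to 2, the recovered-density RMSE on random 256×256 images
is ≈ 0.015 — the quantization floor, not an algorithmic error. Strongly
overlapping stain vectors (real counterstains) raise this floor via the
matrix condition number.

## Labeling detection

Tracer labeling is dark on a light background; raw channels are therefore
inverted (255 − I) so that "high value = labeled" holds in every grayscale
mode, and binarization keeps pixels strictly greater than the threshold
(ties go to background). All five automatic thresholds operate on a 256-bin
histogram spanning the image's value range:

- **otsu** — maximal between-class variance over all splits;
- **isodata** — iteration of `t ← (µ_low + µ_high)/2` from the histogram
  mean to a fixed point;
- **mean** — histogram mean;
- **triangle** — maximal perpendicular distance to the chord from the
  histogram peak to the end of the longer tail, with heights normalized by
  the peak count and positions by the tail length (the algorithm is
  scale-dependent, so this normalization is part of the definition);
- **yen** — maximal Yen entropic criterion.

A constant image has no histogram to threshold and raises a
`DegenerateHistogramError` naming the method; a fixed threshold processes
such images to an empty map instead. The noise filter is a true binary
median: majority vote in the disc `i² + j² ≤ r²` (13 pixels at the default
r = 2), with edge replication at the borders so labeling maps are not
eroded at image edges. Components are found under 8-connectivity by
default (4 available), filtered to a `[min_area, max_area]` pixel range,
and measured: area in pixels and mm² (`area_px · (pixel_size/1000)²`) and
the arithmetic-mean centroid (x right, y down, 0-based, pixel centers at
integers). Injection-site volume is the Cavalieri estimator, Σ area ×
section spacing. Batches of sections with different staining history get
separate parameter sets; the pipeline itself is fully deterministic.

## Atlas volumes and re-slicing

NIfTI-1 volumes are read with nibabel; the affine follows NIfTI precedence
(sform, else qform, else the header fallback) and arrays keep the file's
native voxel order. Voxel coordinates are continuous, 0-based, with voxel
centers at integers. A section plane is `o/u/v`: corner sample `o`, width
vector `u`, height vector `v`, all in voxel space. Output pixel (i, j) of a
W×H slice samples `o + (i·u)/(W−1) + (j·v)/(H−1)` — endpoint-inclusive, so
corner pixels land exactly on `o`, `o+u`, `o+v`, `o+u+v`, and an
axis-aligned anchoring of matching size reproduces a stored plane
bit-exactly. The template is sampled trilinearly (exact for fields affine
in voxel coordinates, which the linear-field phantoms exploit as an
oracle); label volumes use round-half-away-from-zero nearest-neighbor
lookup, since interpolating integer labels is meaningless. Sample points
outside `[0, dim−1]` on any axis return 0, matching the dark background of
MRI templates. `orthogonal_anchoring` builds near-coronal planes for
RAS-like volumes (x mediolateral, y anteroposterior, z dorsoventral),
tilted by pitch about ML and yaw about DV; angles are restricted to the
open interval (−90°, 90°).

## Series anchoring

Between manually anchored key sections, `o`, `u` and `v` are interpolated
*linearly and component-wise* in section index. Spherical interpolation of
the plane orientation was considered and rejected: inter-key angle changes
in real series are a few degrees, where the difference is negligible,
while linear interpolation is exactly testable (vanishing second
differences). Outside the anchored range only `o` is extrapolated (from
the two nearest keys); orientation is held fixed to avoid runaway plane
rotation — a documented choice, since no behavior is prescribed there.
With a single key, neighboring sections are offset along the plane normal
by a nominal spacing (voxel units, default 1.0).

`section_point_to_voxel` uses the same floating-point association as the
slice sampling lattice, so the pixel→voxel round trip with `extract_slice`
is bit-identical. In-plane affine alignment steps compose by absorbing the
2×2 matrix and translation (in normalized image units) into the `o/u/v`
basis; local refinements are pure in-plane translations active inside a
pixel ROI, with overlaps resolved to the smallest-area ROI.

## Coordinate transforms

WHS millimetres come from the NIfTI affine. The stereotaxic transform is
`q = s · R(θ) · P · (p − bregma)`: translate to bregma, apply the signed
axis permutation `P` (identity for RAS-like volumes), rotate by
θ = −4.085° about the ML axis (the flat-skull vs. template pitch
difference; the axis is configurable since only the angle is standard),
and scale uniformly by s = 1.057 (bregma–lambda distance ratio between the
MRI template and the printed stereotaxic atlas). Because rotation and
permutation are orthogonal and the scale uniform, the map is an isometry
times 1.057 — pairwise distances scale exactly, and rotate/scale order is
immaterial. Sign conventions: ML positive right, AP anterior-positive from
bregma, DV negative ventral to bregma. The default bregma position
(0.0, 1.18, 7.10) mm is an **approximate, configurable placeholder**: the
skull landmark is not part of the MRI volume and no authoritative value is
bundled; all shipped checks rely only on transform properties, never on
this default's absolute value.

## Synthetic material

`synthetic_fixtures` renders what the detector assumes about real
material, nothing more. Dense tracer clusters are discs of constant
density 0.9 (terminal fields); "weak fibers" are dilated random-walk
polylines (width ~2 px) at density 0.15, near the noise floor; background
noise is i.i.d. exponential-tailed density on the tracer channel
(scale 0.05 by default), mimicking diffuse non-specific background; the
counterstain is a smooth sinusoidal field (amplitude 0.3) on the second
stain. Planted objects keep a 6-px separation margin so each remains a
distinct connected component. Default images are 256×256 with 4 strong
clusters and 3 weak fibers per section. Everything is deterministic per
seed, and generator-reported areas/centroids are cross-checked against
`measure_clusters` on the noiseless masks.

With Otsu thresholding (threshold ≈ 0.5 density), strong clusters sit far
above threshold — recall is 100 % with sub-pixel centroids — while weak
fibers exceed it only where noise happens to help, so they fragment below
`min_area` and vanish, reproducing the qualitative under-detection of
weakly labeled solitary axons. What these fixtures do **not** model:
staining gradients and batch-to-batch hue variation, the halo around
strong BDA labeling, tissue texture, section deformation, or fiber
morphology — so passing tests demonstrate correctness of the pipeline's
mathematics and bookkeeping, not detection performance on real histology.

Phantom volumes are small (20–32 voxels per axis) with linear or smoothed
random template fields and non-overlapping box/ellipsoid regions; linear
fields make trilinear re-slicing exactly verifiable, and region interiors
(≥ 1 voxel from boundaries) make label assignment unambiguous.

## Problem sizes and numerical choices

The test suite and acceptance script run at deliberately small scale —
256×256 sections, 64×64 oracle images (20 seeds per check), 32³ phantoms,
50 random oblique anchorings, 100–200 random points for transform round
trips — sizes at which every brute-force oracle (exhaustive threshold
search, stack-based flood fill, closed-form affine fields) is exact and
fast. Tolerances: 1e-9 for geometry/transform identities (float64
round-off at these magnitudes), 1e-12 for interpolation second
differences, 0.02 density RMSE for the quantization-limited deconvolution
round trip, 0.5 px for detected centroids, and a perimeter-proportional
band for detected areas (boundary pixels are the only ones thresholding
and median filtering may legitimately move).

## Known limitations

- Stain vectors for the named tracer/counterstain combinations are
  placeholders; real-data parity requires acquiring vectors from the
  material itself.
- Registration is affine-by-construction (plane placement plus in-plane
  affine); no nonlinear deformation of sections is modelled.
- Only scalar template and integer label volumes are re-sliced; DTI
  vector data would need reorientation, which is out of scope.
- Manual labeling-strength categories (high/modest/low) are a human
  judgment and are not reproduced; the weak-fiber behavior is exercised
  only qualitatively (weak recall ≤ strong recall).
- The bregma default and the WHS axis conventions must be configured to
  match the actual volume orientation; no automatic reorientation is
  attempted.
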