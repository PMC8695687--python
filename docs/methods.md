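# Methods

This note records the models, conventions and numerical choices behind
`electrolocate`, in the spirit of a methods appendix: what each step
assumes, which parameters matter, and what the synthetic phantom does
and does not establish about real data.

## Coordinate conventions

World coordinates are RAS millimetres (+x right, +y anterior,
+z superior); voxel indices are 0-based; the NIfTI affine maps voxel
index to world mm. All electrode arithmetic happens in world mm.
Volumes are reoriented to RAS by axis permutation/flip only (world
positions unchanged) and resampled to an isotropic working resolution,
0.4 mm by default, with interpolating cubic B-splines (prefiltered, so
polynomials up to degree 3 are reproduced away from boundaries).
Label volumes always use nearest-neighbour interpolation. Reslicing
fills out-of-field voxels with the input minimum (≈ −1000 HU for CT)
so padding can never masquerade as a metal artifact.

ACPC alignment is a pure rigid motion fixed by three landmarks: the
anterior commissure maps to the origin, the posterior commissure onto
the −y axis (anterior positive), and the midsagittal point into the
x = 0 plane, with z completing a right-handed frame. Target-frame sign
conventions are a choice, not a measurement; this one matches common
neuroimaging practice.

## Surfaces

The brain mask is `(gray + white) > 0.95` with all but the largest
26-connected component removed. Both surfaces are marching-cubes
isosurfaces at level 0.3 of the box-filtered mask — a 3-mm cuboid
kernel for the display/interior surface, 10 mm for the projection
surface. Kernel width in voxels is `round(width/voxel)` forced odd.
Note a geometric consequence used by the tests: a width-w box filter of
a step boundary crosses 0.3 at 0.2·w *outside* the mask, so both
surfaces sit slightly proud of the tissue boundary, the projection
surface by ≈2 mm — which is what makes it a brain-shift projection
target. Enclosed ventricle remnants are removed by DBSCAN over the
vertices (eps = 3× median edge length, min_samples = 10; both
exposed), keeping the largest cluster; ties break to the cluster
containing the lowest vertex index.

Triangle-mesh queries (closest point on a triangle via the standard
seven-region decomposition, Möller–Trumbore ray casting, inside tests
by ray-crossing parity) are implemented in `_trimath.py` with numpy,
with a 2-D hash grid over triangle bounding boxes for candidate lookup.
Voxel-grid interior masks rasterize triangles into grid columns and
fill by crossing parity; ray origins carry a tiny irrational jitter so
exact edge/vertex hits have measure zero. `trimesh` handles mesh
bookkeeping (watertightness, consistent outward winding, PLY I/O).

## Detection

Thresholds: 21 values evenly spaced from the 99th to the 100th
percentile of all CT voxels (linear interpolation between order
statistics). Per threshold, components of `ct > t` under
26-connectivity are kept if

- the component's intensity-weighted-centroid voxel lies inside the
  projection surface (testing the centroid rather than every voxel
  keeps contacts that abut the surface),
- voxel count > 6, and
- volume < that of a 2-mm-radius sphere (4π·2³/3 ≈ 33.5 mm³).

Stable segments are maximal runs of consecutive thresholds whose counts
differ pairwise by ≤ 5. The working threshold is the center element
(lower middle for even length) of the segment whose *maximum* count is
largest; ties go to the longer segment, then the lower threshold. The
stability wording admits other readings (range-within-segment; segment
sum); the pairwise/max reading is fixed here and enforced against an
independent brute-force re-derivation in the tests. Detections closer
than 1 mm are deduplicated by keeping the brighter contact (greedy, in
descending mean intensity — idempotent by construction), and the list
is capped at the 250 brightest.

Weighted centroids use raw CT intensities without background
subtraction. Consequence: detection is *set*-invariant under positive
affine intensity maps (percentile thresholds are equivariant), but an
additive offset perturbs centroids at the 10⁻⁴ mm level — irrelevant
at 0.4-mm voxels, and the reason the invariance test asserts equality
at 10⁻³ mm rather than machine precision.

Manual placement thresholds a cube of side 6× the contact radius
around the click and returns the nearest component's weighted centroid
(or the click itself in draw mode).

## Geometry correction

Grid projection estimates the local grid normal as (mean row
direction) × (mean column direction) from labelled neighbours
(one-sided differences at edges), then casts rays along ±normal and
takes the nearer surface hit; contacts already on the surface (within
1 µm) stay put, and a missing hit falls back to nearest-point
projection. Strips use nearest-point projection directly. Manual
projection vectors: from the mid-commissural point through the contact;
the current view direction; or the surface normal at the nearest
surface point. All projected electrodes retain their original position.

SEEG spacing correction fixes the deepest contact and, for k = 2…n,
moves contact k to the nominal spacing from the corrected contact k−1
along the normalized *vector mean* of the directions from corrected
k−1 to the original contacts k and k+1 (only k for the last contact).
Averaging before versus after normalization was an open choice; vector
mean then normalize is used. Every corrected gap equals its nominal
spacing exactly (to 1e-9 in the tests), and on jittered straight leads
the corrected path is never more bent than the input. There is no
curvature model: a lead with a genuine large bend is corrected
segment-by-segment and will straighten incorrectly — a known failure
mode, inherited deliberately.

Inline projection returns the minimal rotation about the lead midpoint
bringing the first→last contact vector into the viewing plane
(φ = −atan2(u·n, |u×n|) about the axis u×n). A lead parallel to the
plane normal rotates 90° about a deterministic perpendicular axis (the
least-aligned world axis crossed with the lead).

## Tissue classification and atlas labels

A contact samples the voxels within its 1.3-mm radius sphere (world
distance to voxel centers). The unknown rule — both gray and white
sphere means < 0.1 — is evaluated *before* the test so out-of-brain
contacts never reach it; the rules are mutually exclusive in practice,
so the ordering does not change in-brain outcomes. Otherwise a
two-sided Wilcoxon rank-sum test compares the gray and white samples:
p < 0.001 assigns the class with the higher median, otherwise gray.
The p-value uses exact enumeration of all C(n+m, n) splits of the
pooled midranks when both samples have ≤ 10 voxels, and the normal
approximation with tie and continuity corrections above that.

Deformation fields store, for each voxel of their source grid, the
absolute target-space coordinate in mm (not a displacement). Fields
are sampled trilinearly; atlas volumes nearest-neighbour. Point
warping and atlas pull-back both consume the patient-grid field of MNI
coordinates: each patient voxel/point is sent to MNI and the atlas is
read there. The modal label over the warped 1.3-mm sphere counts
background voxels (a flag disables this); if background wins the
contact is "unlabelled" rather than forced to the best tissue label.
Modal ties break to the lower label index. The probabilistic list over
the warped 1-cm sphere stores all per-label fractions (summing to 1,
sorted descending); the matching utility drops entries under 5%.

## The phantom

The phantom emulates the pipeline's inputs, not CT physics. A head is
an ellipsoidal brain (white core, gray shell of configurable
thickness) at soft-tissue intensity (40 HU) in air (−1000 HU), wrapped
in a skull shell at 1500 HU separated from the brain by a 4-mm gap.
Contacts are isotropic Gaussian blobs peaking at 3000 HU with
FWHM = 2× the 1.3-mm contact radius, planted along straight leads or
planar grids; by construction the skull occupies well over 1% of the
volume, so the 99th CT percentile sits at skull intensity and the
threshold sweep brackets the blobs. Tissue maps are the smoothed
core/shell indicators (gray+white ≤ 1). The phantom's "MNI" space is
the patient grid under a fixed anisotropic-scale+translation affine, so
the forward/inverse deformation fields have a closed-form oracle, and
the atlas is a blockwise octant labelling of MNI coordinates. The
truth record carries every planted position, its tissue compartment
(with a 2-mm interface margin; contacts inside the margin are flagged
"boundary" and exempt from exact-recovery checks) and its octant label.
All randomness flows through one seeded generator; a fixed seed
reproduces the volumes bit for bit.

What phantom-based passes do **not** show: robustness to metal streak
artifacts, beam hardening, anisotropic CT slices, cortical folding
(partial-volume mixing at gyral scales), imperfect segmentations, or
non-affine deformation fields. They do establish the correctness of
the detection logic, the threshold rule, the geometric corrections and
the label plumbing under controlled conditions.

Default study conditions: 0.4-mm voxels on a 128×128×112 grid with
brain semi-axes (22, 24, 20) mm and three leads (8+8+10 contacts, one
with grouped 3.5/7-mm gaps). The test suite additionally uses compact
variants (0.5–0.6-mm voxels, semi-axes ≈(20, 22, 18) mm, randomized
2–6 leads of 6–10 contacts) chosen once as the suite's problem sizes,
with the same intensity model throughout.

## Export

Electrode tables are plain text: `electrodes.tsv` with BIDS-iEEG core
columns (name, x, y, z, size) and `eloc_`-prefixed extensions
(channel, MNI coordinates, tissue class, one modal-label column per
atlas); `electrodes.json` with the probabilistic label lists, schema
version and provenance; `channel_map.tsv` restricted to
channel-assigned electrodes and sorted so row index equals channel
number. Floats are written with `repr` (shortest round-trip), so
reload reproduces coordinates exactly. Channel assignment itself is an
input (a label→channel mapping), not a UI.

## Known limitations

- Straight-lead assumption in spacing correction (above).
- Grid projection slightly expands intercontact spacing on curved
  surfaces (normalized spacing ≈1.0–1.2 on tangent grids); no
  distance-preserving (energy-minimizing) projection is attempted.
- The stable-segment reading of the threshold rule is one of several
  defensible interpretations; it is pinned down by tests, not by an
  external reference.
- Detection assumes contacts are resolvable blobs: contacts fused in
  the CT (spacing ≲ 2× blob radius at the working threshold) merge
  into a single component and fail the size filter or yield one
  centroid.
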