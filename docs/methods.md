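# Methods

This note records the models, conventions, parameter choices and known
limitations behind `fibmorph`. It documents what the code computes; every
number quoted here is produced by the test suite or `scripts/acceptance.py`,
not asserted from elsewhere.

## Coordinate and unit conventions

Meshes live in world (physical) nanometre coordinates, never voxel indices.
All biologically meaningful thresholds in this domain are physical (the 30 nm
and 90 nm proximity criteria), so unit ambiguity is excluded at the data
model. Computation stays in nm throughout; conversion to µm² / µm³ happens
once, at the reporting boundary. Volumes are reported as absolute values
(meshes may arrive inward-oriented); the signed value is retained as a
diagnostic field.

## Mesh model and STL I/O

A `TriangleMesh` is an (n, 3) float64 vertex table and an (m, 3) index table
whose winding defines outward normals. STL is read in both dialects; because
"solid"-prefixed binary files are common, the binary layout check
(`size == 84 + 50·n`) wins over the keyword. Vertices are deduplicated by
exact bit-equality on read — STL from a single writer repeats coordinates
exactly, and only deduplicated meshes have detectable shared edges. Tolerance
welding is a separate, explicit pass (`weld_vertices`) with a caller-chosen
epsilon, for meshes from writers that perturb coordinates.

Validity is defined combinatorially: watertight iff every undirected edge is
shared by exactly two faces; consistently oriented iff each such edge is
traversed once in each direction; components are connected faces via shared
edges.

## Surface, volume, orientation repair

Surface area is the summed half cross-product magnitude per triangle
(orientation-independent; degenerate triangles contribute zero). Enclosed
volume is the absolute sum of signed origin-tetrahedron determinants, which
requires watertightness (enforced, with a diagnostic citing the validity
report) and consistent orientation (repaired by breadth-first winding
propagation per component). Components are measured separately and summed by
absolute value, so a file holding several disjoint organelles — the common
per-compartment export convention — measures as the sum of its parts even if
individual components are inverted.

Verified invariants: unit-cube surface and volume are exact; an icosphere at
subdivision 4 is within 0.12% / 0.22% of the sphere closed forms; rigid
motions change results by < 1e-6 relative; results match an independent mesh
library's area/volume to 1e-10.

## Reconstruction: labels → measurement-ready meshes

A compartment's binary mask is zero-padded by one voxel (guaranteeing closure
even when a component touches the volume border) and isosurfaced with
marching cubes at level 0.5, scaling vertices by the voxel pitch into nm.
Nested compartments are merged into their parent's mask before meshing (a
pyrenoid is part of its plastid; meshing the plastid without it would carve a
spurious internal cavity).

Raw marching-cubes surfaces carry staircase artefacts that inflate surface
area. The default post-processing is 10 iterations of Taubin λ/µ smoothing
(λ = 0.5, µ = −0.53, uniform graph Laplacian), which removes staircase while
approximately preserving volume (≤ 3% drift on test spheres, typically
≪ 1%). Surface area of voxel-derived meshes remains biased high by ~1–2% at
the organelle radii used in the tests; the analytic-accuracy statements in
the test suite therefore distinguish parametric meshes (sub-percent accuracy)
from voxel-derived ones.

Isolated islands — disconnected fragments from segmentation debris — are
dropped below a face-count threshold (default 50), with the largest component
always kept.

### Decimation

Simplification to a target fraction of faces (default 25%) uses quadric edge
collapse: per-vertex sums of area-weighted plane quadrics, a lazy binary heap
of candidate collapses with optimal-position solves (endpoint/midpoint
fallback when the 3×3 normal system is near-singular), a link condition
guarding manifoldness, and a normal-flip guard. Error-driven collapse is the
only family of simplifiers that can honour a "morphometrics unchanged"
contract, and the contract is enforced rather than assumed: after reaching
the target the implementation re-measures and aborts if volume drifted > 1%
or surface > 2% (configurable). Measured drift on a 5120-face icosphere
reduced to 1280 faces: 0.28% volume, 0.08% surface. Morphometrics are
measured after decimation by default; passing `decimate_mesh=False` measures
the full-resolution surface instead.

## Proximity surfaces

Distances are surface-to-surface: for each source vertex, the exact
point-to-triangle minimum over the target mesh (interior, edge and vertex
closest-point cases), not vertex-to-vertex, which overestimates on coarse
meshes. The query is accelerated with a k-d tree over target-triangle
centroids: the distance to the nearest triangle's surface is a valid upper
bound, and triangles whose centroids lie beyond that bound plus the largest
centroid-to-corner spread provably cannot win, so the pruned result equals
the brute-force scan (asserted to 1e-9 in tests).

A vertex within threshold contributes one third of its incident face area
(barycentric vertex area), a partition that sums exactly to the total surface
— guaranteeing the fraction tops out at 100%. A stricter variant counting
only faces with all three vertices within threshold is available
(`area_mode="face"`) for sensitivity analysis. The plastid is always the
source surface; membrane thickness is not subtracted. On two icospheres
(r = 1000 nm) separated by a 50 nm gap, the measured fraction within 90 nm is
1.065% against the spherical-cap closed form 1.044% at subdivision 5
(error 0.02 percentage points), and 0 within 30 nm, since the gap exceeds it.

Condition comparisons report the percent change of the proximity fraction; a
zero baseline makes the change undefined and is flagged rather than reported
as a number.

## Image-side pipeline

Stacks are (z, y, x) grids with per-axis voxel size carried in a sidecar JSON
(TIFF resolution tags are unreliable across writers). Registration is
integer-pixel template matching: each slice is translated by the shift
maximizing normalized cross-correlation with the previous aligned slice
(running registration; a fixed-template mode exists for validation), searched
within ± radius. Because the template is the previously *aligned* slice, the
correction for slice k is the absolute accumulated drift, and the search
radius must cover it. Sub-pixel refinement is deliberately out of scope.
Shifts can be estimated on a Gaussian-smoothed copy (`presmooth_sigma`,
default off; 1 px in the pipeline) — detector noise jitters the correlation
peak by ±1 px otherwise — while translations are applied to the original
data. Out-of-frame pixels are filled with the slice median; consumers should
crop to the common field before segmenting, as the pipeline helper does.

Denoising is per-slice (FIB-SEM noise is per-exposure; a 3D median would blur
across the milling axis): either Gaussian blur plus unsharp masking
(`out = blur + amount·(blur − blur₂)`, blur₂ at 2σ; defaults σ = 1 px,
amount = 0.5) or a 2D median (odd window ≥ 3, default 3). The species in this
domain differ in staining contrast, so the method and parameters are
per-dataset choices, configurable throughout.

Segmentation is priority thresholding: an ordered list of (label, intensity
interval) classes, first match wins, followed by removal of 26-connected
components smaller than a voxel-count threshold. This is a deliberately
automatic stand-in for interactive, manually curated segmentation; the
priority order lets nested compartments (brightest, innermost) win their
parent's interval. Intensity convention: higher value = more stained
(backscatter contrast), with inversion handled at ingest.

## Synthetic cells and the comparative study

The generator builds cells from parametric solids with closed-form surface
and volume: spheres, ellipsoids (surface via Legendre incomplete elliptic
integrals; spheroid and near-sphere limits handled), and capsules.
Voxelization is by centre-of-voxel inclusion — unambiguous ground truth
matching threshold-segmentation semantics — and the manifest records analytic
volumes/surfaces, voxel counts and prescribed inter-organelle gaps, enough to
score every downstream stage. Containment and disjointness are verified at
voxelization (nested compartments exempt); prescribed surface gaps are
validated against closed-form pair distances (sphere/capsule combinations).

The standard cell is a sphere with a plastid (16% of cell volume, with a
nested pyrenoid at 8% of plastid volume), a nucleus (5%), and a mitochondrion
whose volume is a fixed fraction (default 0.12) of the plastid's — the
volumetric coupling between the energy organelles that the correlation
analysis is designed to recover. The mitochondrion is placed at an exact
prescribed surface gap from the plastid, swung toward the cell periphery.
These per-organelle fractions sit inside the occupancy ranges reported for
real phytoplankton (plastid 15–40%, nucleus 5–15%, mitochondria 2.5–5%), but
the three-organelle total (~23%) is below the 40–55% typical of real cells:
spherical organelles cannot pack that densely, which is a stated limitation
of the phantom, not of the measurement chain. A separate high-occupancy
fixture — a prolate ellipsoid cell with three ellipsoidal organelles strung
along its long axis, the only way to realise these fractions disjointly —
prescribes occupancies of exactly (30%, 10%, 4%) for occupancy-recovery
tests.

The default comparative study mirrors a multi-taxon design: three replicate
cells (±5% radius jitter) for each of six size presets spanning 2–200 µm³
cell volume, with log-normal noise (cv 5%) on the mitochondrion:plastid
coupling. Grids are kept at 64 voxels across the cell diameter — the voxel
pitch scales with the preset (31–114 nm) so the label grids stay tractable
while organelle diameters remain 15–35 voxels, enough for ≤ 3% volume
recovery (measured: ≤ 1.8% worst-case across 90 compartment measurements).
Prescribed gaps are 3 voxels so that one-voxel gap recovery is a meaningful
test at every preset scale.

Rendered stacks assign per-label mean intensities (background 30, cytosol 80,
nucleus 120, mitochondrion 160, plastid 200, pyrenoid 230 on an 8-bit-like
scale), Gaussian noise (default σ = 10), and a seeded, bounded random-walk
drift (step ≤ 3 px, total ≤ 6 px) applied by cropping each frame from a
padded specimen canvas — content slides in from outside the nominal frame, as
in a real acquisition, rather than leaving constant-fill bands. The resin
background carries a bounded (±12), z-constant texture: the persistent
landmark pattern that slice-to-slice template matching locks onto, without
which registration of slices outside the cell is ill-posed. Bounding the
texture guarantees it cannot cross the background/cytosol threshold, so
zero-noise segmentation remains exact. What the phantom does not emulate:
curtaining artefacts, charging, focus drift, plane-to-plane texture
decorrelation, membrane sub-structure (thylakoids, cristae), and partial
voluming; conclusions from passing tests are about the measurement chain, not
about segmentation difficulty on real contrast.

With these defaults, registration recovers the negated drift trace exactly at
zero noise (10/10 seeds tested) and within ±1 px at default noise, and the
full image path (render → align → crop to common field → median filter →
segment → reconstruct → measure) recovers analytic volumes within 1.4% and
the prescribed gap within half a voxel.

## Statistics

Only descriptive statistics and ordinary least squares are provided, matching
how morphometric studies of this kind report: group mean ± sample sd (n−1;
groups of three cells make the unbiased convention matter), OLS slope,
intercept and R² = 1 − SS_res/SS_tot. Exclusion of an outlying taxon (a cell
two orders of magnitude larger clusters the scatter into two blobs and masks
the within-group relation) is by explicit tag list, never automatic outlier
rejection, and is recorded in the result. The organelle-coupling fit is
offered both on absolute volumes and per-cell-normalized volumes (volume
fractions), since both readings are scientifically meaningful; callers label
which they report. Condition comparisons propagate relative errors in
quadrature onto the percent change. No hypothesis testing is added.

Bundled reference tables carry published per-species mean volumes (three
cells per species) from a comparative FIB-SEM study of phytoplankton, for the
four pyrenoid-bearing taxa, plus the low/high-light occupancy comparison for
the diatom. They support recomputing derived ratios — e.g. the
pyrenoid/plastid volume ratio 100·0.8/11.0 = 7.27% against the reported
7.1 ± 1.2% for the diatom — but not per-cell correlations: the underlying
per-cell tables are distributed as that study's supplementary data and are
not redistributed here. A ratio of means also differs from a mean of
per-cell ratios; for the smallest taxon (relative spread ~60%) the
recomputed 10.0% deviates from the reported 7.2 ± 1.2% for exactly that
arithmetic reason.

## Numerical and degenerate-input policy

* Degenerate (zero-area) triangles contribute zero area and are dropped at
  STL ingest when their indices collapse.
* Ties in the registration search break toward the smaller shift, making
  alignment deterministic.
* Overlapping threshold intervals resolve by list order (first match wins),
  a stated tie-break rather than an error.
* Decimation's optimal-point solve falls back to the better of the two
  endpoints and the midpoint when the quadric is singular (planar or
  symmetric neighbourhoods).
* CSV floats are written at six significant digits, so identical runs are
  byte-identical; all randomness flows from explicit seeds (no global state).

## Problem sizes

Defaults were chosen so the whole validation battery runs on a single CPU in
minutes: the comparative study uses 18 cells on ~96³ grids (~2 min), the
image-path roundtrip one 124-slice stack (~20 s), and the proximity oracle
icospheres at subdivision 5 (~20k faces, ~15 s). All sizes are parameters;
larger runs only change runtime.
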