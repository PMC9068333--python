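# Methods

`laaoplan` implements the measurement side of an automated multislice-CT
(MSCT) analysis for left atrial appendage occlusion (LAAO) planning. The
deep-learning landmark detectors that such a system runs in production are
deliberately out of scope: they are replaced by a predictor contract
(`laaoplan.predictor.Predictor`) with oracle reference implementations, so
that every stage downstream of inference — label encoding, geometric
decoding, clinical measurement, evaluation — is exercised end to end
without GPUs or patient data.

## Representations

All geometry lives in a right-handed world coordinate system in
millimetres. Grids are axis-aligned; voxel indices are 0-based and a
voxel's world position is its centre (`world = origin + index * spacing`).
Preprocessing (isotropic resampling, resize, crop) preserves the world
frame, so landmarks decoded on any preprocessed grid are directly
comparable to ground truth; the `GridTransform` objects returned by
resize/crop make this mapping explicit and composable.

Four landmark kinds are supported, mirroring the four detection task types:

* **Segmentation** — the left atrium + appendage (LA(A)) blood pool as a
  binary label mask.
* **Point** — e.g. the mitral-valve centre; encoded as a labelled sphere
  (default radius 5 mm), decoded as the centroid of the thresholded
  detection after largest-connected-component cleanup.
* **Closed curve** — mitral annulus, fossa ovalis; encoded by sweeping a
  sphere along the curve (default tube radius 3 mm, exact point-to-segment
  distance, voxel-centre membership), decoded by skeletonising the tubular
  mask, building a graph of skeleton voxels with Euclidean edge weights,
  and extracting the long cycle: shortest path between the two
  graph-farthest nodes, removal of its interior, shortest return path. An
  open tube yields an open curve with a warning. The label radii are
  application-dependent configuration, not asserted constants.
* **Plane** — anatomical ostium and device landing zones; encoded by
  splitting the blood-pool mask into two labels by the plane's signed
  distance (label 2 = appendage side when the tip is known, else the
  positive-normal side), decoded by collecting the midpoints of
  face-adjacent (6-neighbour) voxel pairs with labels (1, 2) and fitting a
  total-least-squares plane (smallest principal direction of the boundary
  cloud; near-degenerate spectra are tie-broken lexicographically and
  flagged). Face adjacency gives a thinner, less biased boundary cloud
  than 26-adjacency.

Probability masks are binarized with an inclusive threshold
(probability >= threshold → label 1; default 0.5). Segmentations can be
refined classically: `largest_component` (default) or a marker-based
watershed on the intensity-gradient magnitude, with markers from the
eroded mask and the complement of its dilation; how the watershed result
combines with the network mask (intersect/union/replace) is configuration,
and the result is always confined to a small dilation band of the input so
refinement cannot wander from the network's detection.

## Measurements

At each detected plane the appendage boundary is the closed intersection
polygon of the blood-pool iso-surface with the plane; when the plane cuts
several structures, the polygon whose centroid is nearest the plane's
point is used and the others are kept in the report for audit. From the
contour four diameters are derived: area-based `2*sqrt(A/pi)`,
perimeter-based `P/pi`, maximum = rotating-calipers diameter, and
minimum = rotating-calipers width of the convex hull. The caliper
definitions are the standard unambiguous reading of "minimum/maximum
diameter"; whether they should instead pass through the centroid is noted
as an open modelling choice in the report metadata.

The iso-surface is *not* marching cubes on the raw binary mask: that
staircase surface inflates perimeters by ~9 % and biases caliper widths
low by several percent. Instead the binary mask is linearly upsampled ×2
and Gaussian-smoothed (σ = 1 original voxel), and the 0.5 level set of the
smoothed indicator is meshed. For locally flat boundaries this level set
sits on the true surface; residual curvature bias is O(σ²κ), well below a
voxel for the structures measured here.

Two device-specific appendage depths are computed. The **Amulet depth**
casts a ray from the ostium cross-section centroid along the plane normal
(into the appendage; the direction is auto-flipped if it immediately
leaves the pool) and returns the first 0.5-crossing of the trilinearly
interpolated mask — the "roof" operationalised as the first surface exit.
The **Watchman FLX depth** is the Euclidean distance from the landing-zone
centroid to the appendage tip. When no tip is supplied it is estimated as
the foreground voxel beyond the ostium plane that maximises the intramask
geodesic distance from the ostium centroid, so that bent appendages
resolve to the anatomically distal point. The geodesic uses single-source
Dijkstra on a 5×5×5 primitive-chord stencil (chords admitted only when
their midpoint is inside the mask): a plain 26-neighbour walk overstates
oblique path lengths by up to ~3 %, enough to move the farthest point
around a blunt cap by several millimetres.

## Evaluation metrics

Segmentations are compared by the Sørensen–Dice coefficient
(`2|A∩B|/(|A|+|B|)`, two empty masks defined as 1). Points by Euclidean
distance. Curves by the symmetric Hausdorff distance (curves are densified
to ≤ 0.5 mm vertex spacing first so vertex density cannot bias the
metric), by the distance between arclength-weighted centroids, and by the
signed perimeter-based diameter difference (predicted minus reference).
Planes by the unsigned angle between normals (a plane equals its
flipped-normal twin, so the angle lives in [0°, 90°]) and by the distance
between the centroids of the boundary contours in the two planes.
`tabulate_comparison` aggregates per-case records into the
mean ± sample-SD (n−1) layout used for observer-variability reporting,
reporting empty cells as `n/a` rather than dropping them.

## The phantom

The synthetic generator replaces the patient cohort: a bright ellipsoidal
chamber (contrast-filled left atrium, semi-axes ≈ 26×22×20 mm, varied
±8 % per case) with a tubular appendage swept along a centreline that runs
straight for ≈ 40–50 mm and then bends through 60–80° with 16–20 mm
radius. The tube is the union of spheres with a linearly tapering radius
(≈ 12 mm at the root to ≈ 4 mm at the tip). Intensities are a two-level
indicator (background 50, blood pool 400, roughly HU-like), blurred with a
0.8 mm Gaussian PSF and corrupted with additive Gaussian noise (σ = 15).
The battery grid is 0.75 mm isotropic over a ≈ 128 mm field of view — the
sub-millimetre regime of contrast cardiac CT. Sampling coarser than this
measurably degrades the caliper minimum diameter: at 1.0 mm voxels the
surface position is ambiguous by ±0.5 mm per side and the min-over-
directions width acquires an irreducible −2…−4 % bias, which is why both
the phantom battery and the pipeline default to 0.75 mm for every task.

Ground truth is exact where a closed form exists: the ostium and landing
planes lie on the straight tube segment with normals along the local
tangent, so their cross-sections are circles of radius
`r(s)/sqrt(1−m²)` for taper slope `m` (the normal section of a cone of
spheres), giving analytic area, perimeter and all four diameters. The
mitral annulus and fossa ovalis are planar ellipses; the mitral-valve
centre is the annulus centre. Two truth quantities have no closed form on
a bent appendage and are evaluated numerically at generation time: the
Amulet depth (0.02 mm ray marching through the analytic pool indicator)
and the appendage tip (the geodesic-farthest point of the truth mask —
for a bent, blunt-capped tube this is genuinely a point on the outer
distal rim, not the cap apex).

`perturb_truth` models imperfect predictions for robustness testing:
plane tilts and translations of exactly the requested magnitude in a
seeded random direction, i.i.d. Gaussian vertex jitter for curves, and
mask erosion/dilation. The perturbed *oracle predictor* additionally
blurs hard masks into soft probabilities, adds false-positive voxel
speckle, and — deviating from i.i.d. vertex jitter — displaces curves
with a spatially smooth (circularly low-pass-filtered) field of the
requested RMS amplitude, because a detection network mislocates the whole
annulus band rather than roughening it vertex by vertex; i.i.d. jitter at
1 mm makes the swept tube self-intersect, which is not an error mode the
decoder should be graded on.

### What the phantom does and does not show

The phantom has smooth, convex-ish cross-sections, a single appendage
lobe, no trabeculation, no neighbouring contrast-filled structures
(pulmonary veins, ribs), and no contrast-timing artefacts. Passing tests
therefore demonstrate that the encode→decode→measure chain is correct and
stable under voxelisation, blur, speckle and moderate geometric error —
not that a trained network would reach any particular accuracy on real
morphologies (chicken-wing, windsock, cauliflower appendages).

## Pipeline and provenance

`run_case` orchestrates: isotropic resampling (per-task spacings, all
0.75 mm by default, cached per spacing); segmentation → binarize →
refine; mitral-valve centre detection, which positions a 96³-voxel crop
for the annulus task; curve decoding; plane decoding; cross-sections,
diameters and depths; geometry mapped back through the recorded
transforms. Stage failures are recorded as structured warnings and
independent stages continue; a segmentation failure aborts the plane and
measurement stages, which depend on the mask. Reports serialise to JSON
(and CSV rows per plane) with full provenance — configuration, predictor
names, package version — and contain no timestamps, so a rerun with the
same seeds is byte-identical.

## Numerical choices and degenerate inputs

* Binarization threshold 0.5 (inclusive), configurable.
* Voxels exactly on a split plane join the positive-normal side; exact
  label swap under normal flip therefore holds whenever no voxel centre
  lies exactly on the plane.
* `plane_angle` snaps to 0 when |n_a·n_b| ≥ 1−1e−12 to avoid arccos float
  noise on identical normals.
* Curve decoding smooths the cycle with a circular 5-vertex moving
  average; open tubes return `closed=False` plus a warning instead of an
  error.
* Degenerate TLS boundary spectra (tied smallest singular values) are
  tie-broken towards the lexicographically smallest axis and flagged.
* Hausdorff densification step 0.5 mm; analytic comparisons in tests use
  polygons fine enough that chord error is below the asserted tolerance.
* Problem sizes: batteries of 25 phantoms (workflow) and 20 phantoms
  (round trips) at 0.75 mm / 172³, the scale at which the full suite runs
  in minutes on one CPU while keeping every reported effect well above
  discretisation noise.

## Known limitations

* Plane decoding quantises small tilts: a plane within ~2° of a grid axis
  produces a boundary cloud spanning one or two voxel layers, so decoded
  angles for near-axis planes are accurate only to a few degrees — the
  same regime as the interoperator angle variability the workflow is
  measured against.
* Oblique (gantry-tilted) DICOM/NIfTI orientations are rejected rather
  than resampled.
* The minimum caliper width is an extreme-value statistic and remains the
  most voxelisation-sensitive of the four diameters.
* `analyze` in the CLI requires a truth sidecar because only oracle
  predictors ship with the package; a trained model can be dropped in
  behind the `Predictor` protocol without touching the pipeline.
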