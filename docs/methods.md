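# Methods

## The detection representation

A detection is an n×4 *cell mesh*: columns 0–1 are the (x, y) coordinates of
the left side of the cell, columns 2–3 those of the right side; row 0 and row
n−1 are the cell poles, and intermediate rows pair corresponding stations on
the two flanks. Coordinates are 0-based, pixel-centre, subpixel-valued, with
x along columns and y along rows. An import flag (`--one-based`) shifts
tables exported from 1-based tools.

The mesh's closed contour is the left side followed by the reversed right
side. Pole rows frequently duplicate the pole point on both sides; when
building contours, consecutive vertices closer than 1e-6 px are collapsed
(the tolerance is deliberately larger than machine epsilon: analytically
coincident poles come out of float arithmetic ~1e-7 px apart, and
near-duplicate vertices destroy tangent estimates downstream). The inverse
conversion picks the two mutually farthest contour vertices as poles (ties
to the lowest vertex index), splits the outline there, resamples each side
at n arc-length-uniform stations and pairs them row-wise. Farthest-pair is
the standard pole heuristic for rod-shaped cells; note it is a global
property of the outline — on a long thin rectangle it selects diagonal
corners, not edge midpoints, so the conversion is intended for capsule-like
outlines.

## Image preprocessing

Phase-contrast bacteria are dark with a bright halo. All intensity features
are computed on `(max(I) − I) − b`, where the inversion uses the frame's own
maximum (robust across bit depths; only relative intensities matter) and the
background `b` is the mean inverted intensity at pixel centres outside the
union of all filled cell contours of the frame (the plain complement, no
dilation). With no cells, `b` is the whole-frame mean; if the masks cover
the frame the background is undefined and preprocessing fails loudly.

## Feature definitions and numerical choices

26 features per detection; lengths scale with `pixel_size` (µm/px,
default 1.0 → pixel units, since no calibration should be invented for
uncalibrated data).

* **Length** — sum of distances between consecutive midline points
  (midpoints of each mesh row). **Width** — mean of the top third of the
  row widths, `k = max(1, round(n/3))`, rounding half away from zero.
* **Area/perimeter** — shoelace area and closed-loop perimeter of the
  contour. **Circularity** `4πA/P²`, **compactness** `P²/A`, **sphericity**
  `2√(πA)/P`. Sphericity equals √circularity and is 1 for a circle; a
  `sphericity_formula` hook exists should a different convention be needed.
* **Volume/surface** — each inter-row segment is a cylinder; volume uses the
  trapezoid of `r²`, lateral surface the trapezoid of `r`, times the midline
  step. Coincident pole rows contribute zero radius; no end-cap term.
* **Curvature** — per-vertex plane-curve curvature with wrap-around central
  differences on the (deduplicated) contour; max/min/mean of the signed
  values. Reversing traversal negates the sign; a vertex whose neighbours
  coincide (zero tangent) is an error.
* **Contour intensity** — bilinear samples (scipy `map_coordinates`,
  order 1) at the contour vertices; max/min/mean, the number of peaks
  (scipy `find_peaks` defaults: strict local maxima, plateaus counted once
  at their midpoint, linear traversal, no thresholds), and the max/mean of
  the rolling sample standard deviation (window 10, full windows only,
  n−1 normalization).
* **Midline moments** — Fisher skewness and excess kurtosis of the midline
  intensity samples, bias-uncorrected; if the variance is below 1e-12 both
  are defined as 0.
* **Expanded contour / edge gradient** — contours are offset by displacing
  every vertex ±2 px along its outward normal (from wrap-around central
  differences), preserving vertex count and order so the eroded and expanded
  samples stay paired; the edge gradient is the mean of (eroded − expanded).
  Offsetting by normals rather than raster morphology is what makes the
  pairing possible. An erosion that self-intersects *or flips the contour
  orientation* is rejected — the orientation check matters because eroding a
  thin capsule past collapse yields a reversed but still-simple polygon.
* **Interior intensity** — total/max/mean over pixel centres inside or on
  the contour (shapely point-in-polygon on the bounding-box grid).

`extract_features` never raises for a single bad cell: any failing sub-step
(mesh off the image, degenerate geometry, collapsed erosion) yields an
all-NaN feature row plus a logged reason, and the record is retained. Such
rows are dropped before training and counted separately at deployment.

## Synthetic scenes

The generator emulates the study conditions end to end: 512×512 frames,
20 cells per frame, capsule cells with tip-to-tip length 25–55 px and width
9–13 px (≈1 µm wide E. coli at ~100× magnification), background 10 000,
interior depression 3000, Gaussian halo (amplitude 1500, peak 2 px outside
the edge, σ 1.5 px), edge softness 0.8 px, additive Gaussian noise σ 150 on
a 16-bit scale. Cells are placed by rejection sampling with a 4 px clearance.
Meshes are sampled uniformly along the capsule axis (~1 row/px) with
coincident pole rows.

Defective detections, 10% each by default (40% bad overall):

* **truncated** — a contiguous 40–70% run of rows;
* **shifted** — the whole mesh translated 2–5 px in a random direction;
* **merged** — the mesh splices onto the tail of an end-to-end neighbour's
  mesh (a missed division); the neighbour is rendered in the image;
* **adjacent** — the mesh is correct but a second cell is rendered within
  ~1 px of the flank, corrupting width- and edge-sensitive intensities.

A record is *bad* iff its defect type is not none. Perturbations that cannot
produce a simple outline after 10 resamples fall back to the unperturbed
mesh and are truthfully labeled good.

What the model does **not** capture: real phase-contrast optics (PSF, shade-
off, focus gradients), curved/filamentous morphologies, debris, uneven
illumination, annotator disagreement. Passing tests therefore demonstrate
that the pipeline machinery is correct and that the classifier recovers a
planted good/bad distinction; they do not certify accuracy on real
micrographs, where the good/bad boundary is fuzzier. On this generator the
classes are in fact linearly separable, so held-out accuracy sits at the top
of the expected 90–100% band.

## Training protocol

Rows with any missing feature or a missing (Questionmark) label are dropped.
The split is stratified (default 50-50) with a mandatory seed. Model
selection is stratified 5-fold CV accuracy over linear×{C} ∪
RBF×{C}×{gamma} with C ∈ {100, 1000, 10 000} and gamma ∈ {0.001, 0.01, 0.1};
features are standardized inside the pipeline (training mean/sd) — fixed
gamma grids are meaningless across raw feature scales. Ties prefer smaller
C, then linear over RBF, then smaller gamma (the simpler model). The winner
is refit on the full training split.

When the training set exceeds 5000 points (or on request) the RBF candidates
use a Nyström feature map (seeded uniform landmark subset, default
min(1000, n) components) followed by a linear SVC (libsvm, not LinearSVC —
same loss/regularization as the exact machine, so full-rank Nyström
reproduces exact-kernel predictions to ~1e-14 on well-conditioned feature
matrices). `class_weight` (e.g. "balanced") is exposed for imbalanced data.

Evaluation: ROC by threshold sweep on the continuous decision score with
trapezoidal AUC; confusion metrics with zero-denominator cases reported as
NaN with a warning; per-feature bias ratios with a 5% default flagging
tolerance. Probability calibration is not implemented — it adds a stochastic
fit without changing score rankings, and every consumer here (ROC, curation
threshold) is rank- or sign-based.

Persistence is a versioned JSON archive (feature manifest, scaler statistics,
Nyström landmarks/projection, SVM coefficients). Both fresh and loaded
models predict through the same plain-numpy decision path extracted from the
fitted sklearn objects, so a reload is bit-identical by construction, and
prediction rejects inputs whose feature names or order differ from the
manifest.

## Labeling

A headless state machine over the feature table in (frame, cell_id)
ascending order: good→1, bad→0, questionmark→NaN, return steps the cursor
back one record (the old verdict stands until overwritten). Sessions
serialize to JSON keyed by (frame, cell_id) and resume exactly; unvisited
records keep whatever label the table already had. The CLI front-end is a
thin stdin loop over this machine.

## Problem sizes

The default test/validation sizes were chosen to exercise every regime while
staying light: 200-cell scenes for feature and property tests, 800 cells for
the defect-mix concentration check (±5% is ≈3 binomial sd there), 2000 cells
(100 frames) for the end-to-end accuracy run, n=300 for the Nyström
equivalence oracle and 10 000 draws for the null-AUC check.

## Known limitations

* The mesh↔contour conversion assumes elongated, capsule-like outlines;
  farthest-pair pole selection is inappropriate for round or branched cells.
* Vertex-normal offsetting is exact only for smooth contours; detections
  thinner than twice the offset legitimately fail the eroded-contour
  features and fall out as NaN rows (~10% of records under the default
  defect mix, almost all truncated slivers).
* Axis-uniform mesh sampling and arc-length resampling place near-pole rows
  at different stations, so a mesh→contour→mesh round trip preserves the
  outline (Hausdorff < 0.5 px) but not per-row widths near the caps.
* Snapshots only: no tracking, no division detection, no time-lapse linking.
* Single-annotator label semantics; no reconciliation of conflicting labels.
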