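# Methods

This note documents the models, parameter choices and numerical details
behind `cellactivity`, and what the phantom-based validation does and
does not demonstrate.

## Scope and assumptions

The pipeline measures *adherent, non-dividing* cells in 2D gray-scale
time-lapse stacks under three assumptions:

1. **Temporal oversampling.** A cell's per-frame displacement is smaller
   than its radius, so its masks in consecutive frames overlap. All
   tracking rests on this; at the reference acquisition (1 frame/min,
   0.398 µm/px) it holds comfortably for slow-moving cell types.
2. **Contaminants are fast.** Debris and dead-cell fragments drift much
   faster than cells, so a velocity threshold relative to the population
   median separates them.
3. **First-order protrusions.** Protrusions emanate radially from the
   cell body without branching, so they appear as single peaks of the
   unraveled polar contour.

Cell division, lineage, and sub-protrusion structure are out of scope;
cells absent from any frame are excluded by design (full-presence
filter), which also means the pipeline measures a *surviving
population*, not per-frame cell counts.

## Coordinates and conventions

Everything uses (row, col), 0-based, with pixel centers at integer
coordinates. Angles are counter-clockwise from the +col axis in the
(row, col) right-handed frame. Index-map classes: 0 background,
1 contaminant, 2 cell, 3 cell–contaminant overlap, 4 cell edge.

## Segmentation support

The semantic segmenter is a plug point — any callable producing
per-class probability grids; the per-pixel argmax (ties to the lower
class index, i.e. background-favoring) yields the index map. The repo
deliberately ships no trained network: training needs annotated data and
GPU time, and the downstream measurement science is independent of which
segmenter supplies the index maps. What ships instead:

- **Sobel baseline** — gradient magnitude, Otsu threshold, closing, hole
  fill, small-object removal. It cannot split touching cells or reject
  contaminants; it exists as the classical reference and for quick
  looks. If Otsu marks more than 25 % of pixels as edges the frame is
  treated as structure-free (pure noise has no coherent edges);
  otherwise closing would inflate the noise floor into fake objects.
- **Preprocessing** (display/baseline only) — Fourier background
  removal (frequencies below 4 cycles/image removed, DC kept; the input
  is mirror-padded 2× before the FFT to suppress leakage from
  non-periodic trends) followed by CLAHE (clip limit 2 %, kernel 1/8 of
  each image dimension).
- **Annotation consolidation** — tagged binary layers merge with
  precedence overlap > cell > contaminant > background; the cell-edge
  class is the 2-px inner contour band of the cell union; a pixel
  claimed by two cell layers goes to the smaller claimant (logged).
- **Edge-weight map** — `w(x,y) = 1 + w₀·exp(−D(x,y)²/σ²)` with D the
  Euclidean distance to the nearest cell-boundary pixel. The *entire*
  boundary of every cell is used, not only contact zones, which is the
  cheaper and stricter choice for boundary-aware training. w₀ and σ have
  no canonical values (defaults 10 and 5 px; both are pure scale
  parameters of the training loss, not of any measurement).
- **Paired augmentation** — crop, rotation, reflection, warp, swirl,
  applied identically to image and annotation; annotations are always
  resampled nearest-neighbor so no interpolated class labels can
  appear. Rotations are restricted to multiples of 90° so they are
  exactly lossless on the class grid; the continuous distortions (warp,
  swirl) cover arbitrary-angle variability instead.

## Tracking

Islands (8-connectivity; 4-connectivity would sever diagonal protrusion
pixels) below 30 px are dropped as sub-cellular noise at the reference
pixel scale. Labels are 1..K by decreasing area. Overlap propagation
ties break toward larger overlap, then larger island area, then lower
id. Merges (several ids collapsing onto one island) and splits are
recorded as events.

Watershed refinement pairs each merge with the survivor's next split,
re-identifies the reappearing ids by nearest-neighbor matching of
vertices (Hungarian assignment, so no candidate is used twice), and
re-splits every merged frame by watershed on the inverted distance map
seeded at nucleus candidates (distance-map local maxima, minimum
separation half the island's body radius). Merges that never separate
are resolved forward to the stack end; splits with no preceding merge —
adhesion present from frame 0 — are resolved backward. If an island
offers fewer candidates than merged ids it stays merged with a warning;
the watershed always partitions the island exactly, so foreground pixel
counts are conserved.

The velocity filter's factor (3.0 × population median) has no canonical
value; it only needs to sit between the cell speed spread and the
contaminant speed contrast (the phantom default is 5×, leaving margin on
both sides). The detection score is AP = TP/(TP+FP+FN) from greedy IoU
matching at a single threshold (no multi-threshold sweep), averaged over
frames; empty-vs-empty scores 1 by convention.

## Morphology

- **Area**: pixel count × (µm/px)². **Perimeter**: Crofton estimate
  (4 directions) — nearly unbiased on rasterized masks, where edge-pixel
  counting overestimates by up to ~41 % on diagonals. The shape factor
  is exported as P/A (1/µm) — larger means more complex outline — with
  the reciprocal also exported.
- **Vertex**: distance-map argmax (ties: first in scan order), refined
  by an unweighted least-squares isotropic-Gaussian fit on the 11×11
  window (initialized at the maximum, σ₀ = 3 px, parameter tolerance
  1e-6). The fit falls back to the coarse maximum (logged, flagged) if
  the optimizer fails or the fitted peak leaves the window; a window
  clipped by the image border is fitted as-is and flagged. On an exactly
  Gaussian surface the recovery is ~1e-13 px; on real distance maps
  (cone-shaped, not Gaussian) the fit acts as a robust sub-pixel
  interpolator of the peak.
- **Polar contour**: the half-level boundary from marching squares,
  giving a closed, ordered, sub-pixel curve. Distances/angles are taken
  to the refined vertex; the unraveled form indexes by contour position
  rather than angle, so multi-valued radii (overhanging protrusions) do
  not fold over.
- **Protrusions**: peaks of the unraveled path above √2·d⁰, where d⁰ is
  the distance-map maximum (the body radius at the vertex). The √2
  factor means a protrusion must reach ~41 % beyond the body radius —
  high enough to ignore boundary roughness, low enough to catch real
  arms. Peak separation defaults to 5 % of the contour length; circular
  wrap-around is handled by rolling the path to start at its global
  minimum, which can never be a peak.
- **Eccentricity**: ε = d¹/d² from the global nearest and farthest
  boundary points (ties: first in traversal order); ε ∈ (0,1], 1 for a
  disk, decreasing under elongation *or* protrusion growth. Note the
  inverse relation: "more eccentric" in the colloquial sense means
  *smaller* ε. Raw Δd = d¹/d² and Δφ = φ¹/φ² are exported without
  interpretation.
- **Derivatives**: forward differences at the frame interval, no
  smoothing. They are correspondingly noisy; averaging over cells and
  frames is the intended use, not frame-level oscillation analysis
  (which would need a higher sampling rate).

## Migration

Path distance is the polyline arc length over the refined vertices
(sub-pixel, so quantization noise in per-step speeds is far below
0.5 px/frame). Propagation area is the union of the cell's masks over
time — the occupied-territory reading; the convex hull of the *vertex*
track is reported separately by the long-term persistence measure, so
both readings are available.

Directional persistence is a principal-axis ratio (minor/major RMS
extent, ∈ (0,1]) of either:

- **DP_S** — the per-step displacement vectors, with second moments
  taken about the **origin**, not the mean: a steady drift has zero
  variance but is maximally persistent, and origin moments give it
  ratio 0 while an isotropic walk stays ≈ 1. A 16-bin angular histogram
  of headings (weighted by step length) is exported alongside.
- **DP_L** — the vertex-position cloud (central covariance), plus the
  convex-hull area. Collinear or stationary tracks are flagged
  degenerate, never an exception.

Both raw axis lengths are exported with the ratio, so the reciprocal
convention can be recovered exactly. Velocities are reported in both
µm/min and px/frame; defaults are 0.398 µm/px (640 µm field of view at
1608 px) and 1 min/frame.

## Reporting

Population summaries keep per-cell means and pooled per-frame values
separately for six properties (area, shape, eccentricity, protrusion
count, velocity, long-term persistence). Control-relative values are
ratios of per-cell population **means** (medians are also exported but
not used for the ratios); a zero or undefined control mean flags the
ratio NaN rather than producing infinities. No per-property
normalization is applied before the ratio, and no hypothesis tests are
attached — the deliverable is the distributions and their ratios.

## Phantom generator

Phantoms emulate the acquisition the pipeline targets: 8-bit gray
frames at 0.398 µm/px, 1 min intervals, full runs of 360 frames (tests
and validation use 20–50 frames to keep runtimes in seconds — the
geometry is scale-free in frame count). A cell is an ellipse (semi-major
`body_radius`, ratio `axis_ratio`) plus evenly spaced Gaussian angular
bumps for protrusions (width floored so rasterized arms stay
4-connected), optionally breathing via a 3rd-order Fourier radius
perturbation whose phase advances per frame. Rendering paints a 2-px
dark rim around a lighter interior on a mid-gray background — the
bright-field halo contrast that makes the Sobel baseline work — plus
Gaussian pixel noise (sd 2 gray levels). Contaminants are textured disks
moving ballistically at 5× the fastest cell speed (bouncing off borders
so they stay in frame and exercise the velocity filter rather than the
presence filter). Motion models: stationary, linear, random walk, or
fully scripted trajectories (the only sanctioned way to create
adhesion; accidental overlap at frame 0 is an error).

What phantoms do **not** emulate: realistic bright-field texture,
illumination drift, focus changes, cell division, or ambiguous
cell/contaminant appearance. Passing the phantom battery therefore
validates the *measurement* chain (tracking, geometry, statistics)
under known ground truth; it says nothing about segmentation quality on
real images, which depends on the external segmenter plugged in.

## Validation battery (scripts/acceptance.py)

All quantities are recomputed from generated scenes at run time, seeded
from `--seed`: analytic disk/ellipse oracles (≤ 2 % area and perimeter
error, ε within 5 % of 0.5, vertex within 0.5 px, Gaussian peak within
0.1 px), exact protrusion counts for 3–8-armed stars under rotation and
reflection, the 50-frame tracking scene (3 cells retained, 0 identity
swaps), scripted adhesion (both ids in 100 % of frames), programmed
speeds {0,1,2,4} px/frame recovered within 0.5, persistence extremes
(straight < 0.1, seeded isotropic walk in [0.8, 1]), the detection
metric's closed-form cases (1.0, 0.8, 0.0), the weight map's closed
forms (1+w₀ at the edge, 1+w₀/e at σ), and the two-condition experiment
(half speed, double protrusions → ratios 0.5 and 2.0 within 10 %).

## Known limitations

- Overlap tracking has no appearance model; two cells swapping
  positions within one frame interval would swap ids. The oversampling
  assumption is the only guard.
- Watershed refinement assumes merged cells eventually separate (or
  stay merged to an end of the stack); a merge-split chain involving
  three or more cells simultaneously is resolved greedily.
- ε conflates elongation with protrusion growth; separating cell body
  from protrusions is future work.
- The contour-index protrusion detector counts arms, not their lengths.
- Derivative columns (dA/dt, dP/dt, per-step velocity) are unsmoothed
  forward differences and should be aggregated before interpretation.
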