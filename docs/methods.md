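# Methods

`rwcontour` contours six structures on thoracic CT — lungs, airway, heart
(with its adjacent vessels), spinal cord, body outline and the gross
tumor volume (GTV) — from a single user-seeded slice. This note records
the model, its tunable parameters, the numerical choices, what the
synthetic phantom does and does not emulate, and the known limitations.

## Image preprocessing

All segmentation runs on 8-bit images produced by a single global
soft-tissue window: HU in [-140, 260] map linearly onto gray levels
[0, 255]; values outside clamp to 0/255. Rounding is half-away-from-zero
(equivalently half-up on the non-negative scaled values), chosen so the
map is deterministic across platforms; the windowed value for 60 HU is
therefore 128, not 127. DICOM stored values are always converted through
RescaleSlope/RescaleIntercept; series lacking them are rejected rather
than guessed. Volumes are normalized to inferior→superior slice order at
load so that "superior"/"inferior" mean the same thing everywhere in the
pipeline.

## Random-walker segmentation

Each slice is segmented independently on a 4-connected pixel lattice
restricted to a rectangular ROI. Edge weights are the Gaussian function
of the gray-level difference,

    w_ij = exp(-beta * (g_i - g_j)^2),    g in [0, 1],

with gray levels rescaled from [0, 255] to [0, 1] before the exponential:
with raw 8-bit differences, beta = 70 would annihilate all contrast
(exp(-70) underflows), so the parameter is only meaningful on normalized
intensities. A floor of 1e-6 is added to every weight so flat-black
regions remain connected and the Dirichlet system is never singular.

For each seeded category the probability that a weighted random walk
released at a pixel reaches that category's seeds first is the harmonic
function solving the combinatorial Dirichlet problem: the graph
Laplacian restricted to unseeded pixels, boundary value 1 on the
category's seeds and 0 on all others. The sparse symmetric system is
solved by direct LU factorization (SuperLU), one factorization per slice
reused for the K-1 right-hand sides; the K-th field is the complement,
so probabilities sum to exactly 1. Pixels take the argmax label; exact
ties resolve by the fixed priority body < lungs < airway < heart <
spinal_cord < gtv < background. Components smaller than 5 px are
absorbed into their surrounding label to suppress argmax speckle.

Default `beta = 70`. The lattice, weight function and solver are checked
in the test suite against a dense direct solve (1e-8) and a Monte-Carlo
absorption oracle (1e5 walks per pixel). Because the Monte-Carlo check
makes thousands of binomial comparisons, the acceptance test bounds the
worst normalized deviation at the family-wise (Šidák, alpha 0.01)
quantile rather than a pointwise 3-sigma, and additionally requires 99%
of comparisons within 3 sigma; a pointwise 3-sigma bound would be
expected to fail for an exact solver.

### The background category

The six anatomical categories cannot tile the ROI (air outside the
patient belongs to none of them), so a seventh `background` category is
seeded automatically on ROI-border pixels whose windowed gray level is
at most 10, every 5th border pixel by default.

## Seed propagation

The user seeds one slice (1–20 points per category; one point suffices
for the spinal cord). Every other slice is seeded from its already
segmented neighbour, moving superior and inferior from the initial
slice, on the prior that organ cross-sections change slowly at 2–2.5 mm
slice spacing. Per 4-connected component of each category:

* **Boundary erosion.** The component is eroded with a disk of radius
  12 px if its area exceeds 1000 px, radius 1 px otherwise, and seeds
  are sampled uniformly from the eroded region's edge
  (`max(1, round(0.05 * boundary length))`, at most 20).
* **Skeleton.** The component is thinned to a 1-px skeleton, spur
  branches shorter than 5 px hanging off junctions are pruned (one
  pass), and seeds are sampled from the skeleton at the same ratio.

Both sources run on every component: the eroded edge hugs the outline
while the skeleton covers the medial line, so ring-like regions (the
body wall) stay seeded along their whole extent. When erosion
annihilates a thin component — the 2-px chest-wall muscle sheet is the
canonical case — the skeleton is the only source, which is precisely
the seeds-vanishing rescue the scheme was designed around.

**Gray-level knowledge filter.** Candidate seeds are then checked
against the *next* slice's windowed gray level: lungs/airway/background
seeds must be nearly black (g ≤ 10), body/GTV seeds must not be
(g ≥ 10), spinal-cord seeds must not sit on bone-white (g ≠ 255), and
heart seeds must fall in the muscle/blood soft-tissue band
(85 ≤ g ≤ 200, about -7..174 HU). The heart band deliberately excludes
fat: the heart borders mediastinal fat, which passes a mere "not air"
test, and with such a test the tracked heart cannot shrink at its apex
and base — it lingers in fat the organ has vacated. The band follows
the anatomical HU table (muscle/vessel/soft tissue 20–40 HU vs fat
-30..-70 HU) with ±3 sigma of the 20-HU image noise.

If sampling left a component with no surviving seed while admissible
candidate pixels exist, the sample is re-drawn from the admissible
candidates, so a still-present organ never silently loses tracking; a
component vanishes only when no admissible pixel remains (the organ
genuinely ended), and the event is logged.

All sampling randomness derives from a single run seed split
deterministically per (slice, category, component), so reruns are
bit-identical.

## Anatomical constraints

* **Heart gating.** The heart is only active on the user-declared
  [appear, disappear] slice range; heart seeds outside it are dropped.
  The initial slice must lie inside the range so heart seeds can
  propagate outward to both ends.
* **Tracheal junction.** Below the user-declared junction slice the
  airway is expected to consist of two bronchi: when seed propagation
  crosses the junction in the inferior direction a still-single airway
  component is split at its centroid column so each prospective
  bronchus receives its own seeds, and any airway components beyond the
  two largest are absorbed and logged.

## Spinal-cord circle refinement

The thoracic cord is quasi-circular, so the raw random-walker cord label
is replaced each slice by a fitted disk: Sobel edges inside a square
window (half-width 25 px) tracking the cord center, thresholded at the
90th percentile of the in-window gradient magnitude, then a Hough circle
transform over radii 4–12 px (plausible cord calibers at ~1 mm pixels).
The accumulator maximum wins; exact ties resolve to the smallest radius,
then the lexicographically smallest center. Fewer than 10 edge points,
or a fitted center jumping more than 10 px from the previous slice,
keeps the previous circle and flags the slice. The window is re-centered
on the fitted circle every slice; on the first slice it is centered on
the user's single cord seed. Former cord pixels outside the fitted disk
are handed to their nearest non-cord label.

## Contours and outputs

Category boundaries are exported as crack polygons: vertices on pixel
corners at half-integer (row, col) coordinates, outer boundary per
4-connected component, collinear runs merged. Rasterizing a polygon
fills exactly the original component (holes are filled, since only outer
boundaries are exported); pixel centers never lie on polygon edges, so
the round trip is exact rather than approximate. Label stacks are
written as NIfTI with a plain-text id↔category legend; contours as JSON.

## Evaluation

Per category, voxel confusion counts over the slices where the reference
delineates the category give Dice = 2TP/(FP + 2TP + FN) and
FPR = FP / (TP + FN), FNR = FN / (TP + FN). Both rates are normalized by
the reference-positive count — the convention under which an
over-inclusive contour of a small structure can show FPR > 0.5 while
keeping a reasonable Dice, which is how such pairs arise in practice for
the spinal cord. Slices the reference does not contour are excluded from
that category's counts (partial clinical contouring); a category absent
everywhere is reported as not-applicable, never 0. Contour distance is
the symmetric Hausdorff distance max(h(A,B), h(B,A)) between boundary
voxels, in index units and millimetres.

## The synthetic phantom

No patient data ships with the package; every end-to-end test runs on a
generated thorax (default 80 slices of 256x256 at 2.5 x 1 x 1 mm):

* elliptic-cylinder body, fat core (-50 HU) with a muscular rind under
  the skin (30 HU) — real body walls present muscle, not fat, at the
  air interface;
* two ellipsoidal lungs (-500 HU) with a thin muscular pleural lining,
  cradling the heart the way real lungs do;
* an air trachea that widens into two overlapping lumens at the
  junction slice and separates into two walled bronchi (60 HU walls)
  diverging ~1.3 px/slice toward the lungs;
* an ellipsoidal heart (45 HU) restricted to a slice range;
* a 6-px spinal cord (40 HU) inside a bone annulus (700 HU, far above
  the window);
* a soft-tissue tumor (30 HU) strictly inside one lung — deliberately
  lung-adjacent soft tissue, the hard GTV case;
* a detached 2-px chest-wall muscle sheet that erosion annihilates,
  exercising the skeleton rescue path;
* Gaussian noise, sigma 20 HU, everywhere.

Cross-sections vary smoothly slice to slice, matching the propagation
prior. Geometry is specified as shape fractions so the same generator
produces the reduced 44 x 192 x 192 phantom the unit tests and the beta
sweep use; fine calibres (cord, airway, walls, sheet) are absolute
pixels. A `degrade` operation blurs boundaries and raises noise for
weak-edge stress tests, leaving ground truth untouched.

What the phantom does *not* emulate: textured parenchyma, partial-volume
ramps at every interface, contrast uptake, motion artifacts, anatomical
variability, and the ambiguous soft-tissue boundaries (heart vs
mediastinum, tumor vs atelectasis) that dominate clinical error. Passing
the phantom therefore demonstrates that the machinery — solver, seed
propagation, filtering, gating, refinement — is correct and stable, not
that clinical accuracy matches any particular figure; phantom Dice
floors (lungs/body 0.95, heart 0.90, airway/cord 0.85, GTV 0.80) are
deliberately above typical clinical values because the phantom is
easier than patient anatomy.

## Problem sizes and defaults

The package's own checks use: 100 random lattices up to 8x8 for the
solver oracles (1e5 walks per pixel for the Monte-Carlo reference); 50
random blobs for the morphology oracle; 50 rasterized circles with 20%
outliers for the Hough fitter; one full-size phantom run, twice, for the
end-to-end floors and determinism; and the reduced phantom for the beta
sweep {40, 70, 90}, whose lung Dice spread stays below 0.01 — the free
parameter is not critical above ~30, which is why the default sits at
70 between the insensitive-range endpoints.

## Known limitations

* Strictly 2D slice-wise segmentation: no 26-neighbour volumetric
  random walker, by design.
* One global window; per-slice recalibration is not attempted.
* The heart's soft-tissue seed band assumes non-contrast CT; strongly
  enhanced blood pools near the upper bound would need the band moved.
* GTV contouring uses gray level only; clinically the GTV is defined
  with PET and history, so real-data GTV error is expected to be much
  larger than for normal organs.
* No interactive correction loop and no DICOM-RT export.
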