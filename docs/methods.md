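# Methods

## Input model

The unit of analysis is a calibrated label mask: a 2-D grid of class labels
(0 background, 1 mitochondria, 2 ER) plus the physical width of one pixel
in nm. The default calibration, 0.38 nm/px, corresponds to
high-magnification TEM of ultrathin tissue sections; synthetic fixtures use
1 nm/px so that whole scenes stay a few hundred pixels across. Coordinates
are (row, col), 0-based, origin top-left; every distance in the package is
measured between pixel centers. Masks are stored losslessly as
single-channel 8-bit PNG/TIFF (value = class); RGB masks using the common
display convention (mitochondria magenta (255, 0, 255), ER turquoise
(64, 224, 208), background black) are decoded through a palette with a
configurable per-channel tolerance (default 0 — exact colors; raise it for
anti-aliased exports). The calibration travels as a parameter, not as
image metadata, because mask files in the wild rarely carry trustworthy
resolution tags.

## Objects and contours

Organelle objects are maximal connected components of one class,
8-connectivity by default (4-connectivity available); components are
ordered by their top-left-most pixel so object ids are stable across runs.
No minimum-size filter is applied by default.

Each object's external boundary is traced with Moore-neighbor tracing
using Jacob's stopping criterion, starting at the object's top-left-most
pixel and proceeding clockwise. Internal holes are filled before tracing,
so exactly one closed contour represents each organelle — cristae-like
holes inside a mitochondrion do not spawn contours. By construction every
traced pixel touches the outside through a 4-neighbor (or the grid
border). For 1-pixel-thick parts the raw trace passes out and back along
the same pixels; the contour keeps each boundary pixel once, in
first-visit order, because duplicated points would double-count contact
lengths on thin objects. The closing step of such degenerate contours uses
the actual Euclidean distance between last and first point, which keeps
the perimeter of e.g. a 3×3 square at exactly 8 px.

Arc length is the polyline length through pixel centers — unit steps for
orthogonal moves, √2 for diagonal moves — times the pixel size. This
convention is rotation-consistent (a shape and its 90°-rotation have equal
perimeter), unlike pixel counting. Areas default to pixel counts × pixel
area, which is unbiased at pixel resolution and consistent with area
fractions; a shoelace (polygon) area over the boundary polygon is provided
for comparison with contour-based tools. For any filled region the
pixel-count area is ≥ the polygon area (the boundary polygon cuts through
the centers of edge pixels).

## Contact detection

The detector follows the operational definition used in 2-D TEM
morphometry: a mitochondrial contour pixel participates in a MERC when its
distance to the nearest ER contour pixel is below 80 nm, and the contact is
*close* (first type) below 15 nm, *loose* (second type) otherwise. Both
comparisons are strict by default and run in nm: the distance field is an
exact Euclidean distance transform seeded at all ER external-contour
pixels, multiplied by the pixel size. The sometimes-quoted integer pixel
equivalent of a threshold (80 nm = 211 px at 0.38 nm/px, rounding half
away from zero) is exposed as a converter but never used for the
comparison itself, which avoids double rounding.

Per-pixel contact labels on a closed contour are grouped into maximal
*circular* runs — a run spanning the traversal start/end counts once, and
a contour entirely in contact yields a single segment whose length is the
full closed perimeter. Each run of k pixels contributes an arc length of
its k−1 internal steps; this makes the lengths of disjoint segments on one
contour sum to at most the contour's perimeter (equality exactly when the
whole contour is one contact). Two grouping semantics are offered because
the field's verbal definitions are ambiguous: `per_pixel` (default) makes
every maximal run of *same-type* pixels one contact, so a close stretch
flanked by loose pixels produces separate close and loose segments;
`per_segment` merges any contiguous in-contact run and types it by its
minimum distance. Contacts are counted per run on a mitochondrial contour
regardless of how many distinct ER objects are nearby.

Degenerate inputs degrade gracefully: no ER → an all-infinite distance
field and zero contacts; empty masks → all-zero reports.

## Segmentation metrics

Evaluation is pixel-pooled by default: confusion matrices of all images
are summed before metrics are computed (per-image averaging, with
undefined values skipped and counted, is available). Per-class metrics use
one-vs-rest reductions: precision TP/(TP+FP), recall TP/(TP+FN), IoU
TP/(TP+FP+FN), F1 2TP/(2TP+FP+FN), with the identity F1 = 2·IoU/(1+IoU).
A `precision_formula="as_printed"` variant computing TP/(TP+FP+FN) is
exposed for comparability with texts that print that formula; it is
algebraically identical to IoU and therefore not the default. Any 0/0
metric is reported as undefined (`None`), never as 0, so class-absent
images cannot silently drag averages down.

## Area fractions and grid counting

Automatic area fractions are exact pixel counts divided by image size. The
stereological estimator places grid vertices every `spacing_nm` (default
170 nm, a typical manual grid pitch; the spacing is deliberately the
*only* grid parameter, since grid dimension and pitch together would
over-determine the geometry) anchored at pixel (0, 0) by default, with an
optional offset for bias experiments, and labels each vertex by the class
of the pixel it lands on. At one-pixel spacing the vertex lattice is
exhaustive and the estimate equals the pixel-count fractions exactly —
this limit is tested. A second, cell-hit estimator marks a vertex when any
pixel of its s×s cell carries the class; it emulates coarse manual marking
whose minimal countable unit is a whole cell and reproduces the known
overestimation of thin ER, asserted in tests as a trend over ≥100 seeded
scenes rather than per scene.

## Synthetic scenes

The generator emulates the statistical structure of segmented tumor-cell
TEM images: mitochondria as filled ellipses with clear boundaries, ER as
thin elongated tubules, mitochondria covering ~4–5% of pixels and ER ~2–4%
in default scenes. Absolute sizes are scaled down — default scenes are
320×320 px at 1 nm/px with ellipse semi-axes 16–40 nm, versus ~2000²
px at 0.38 nm/px with 0.2–0.4 µm organelles in real micrographs — keeping
per-scene cost at a few milliseconds while preserving the class-fraction
regime and the thin-ER geometry that drive the analysis. What the scenes
do *not* emulate: irregular (non-elliptical) mitochondrial outlines,
branching ER networks, within-contact gap variation (planned tubules
follow the ellipse at constant offset), partial organelles at the image
border, and annotation noise in the ground truth itself. Tests passing on
these scenes therefore validate the geometry and accounting of the
pipeline, not segmentation quality on real tissue.

Placement is rejection sampling with a fixed order (mitochondria → contact
tubules → free ER) under one RNG stream per scene, so a scene is a pure
function of its seed. A planned contact carves the tubule from the annulus
of background pixels whose distance to the target mitochondrion lies in
[gap, gap + width], restricted to a random angular wedge of the requested
arc span, kept clear of other mitochondria and existing ER. The realized
gap is then re-measured on the rasterized mask (minimum contour-pixel to
contour-pixel distance, the same quantity the detector thresholds) and the
placement is retried until it lies within ±0.5 px of the plan; bounded
retries end in a `PlacementError` naming the violated constraint. Free ER
tubules are dilated random-walk polylines confined to the region ≥ 100 nm
(loose threshold + margin) from every mitochondrion, so they can never
register as contacts. Scenes for threshold-recovery experiments use one
mitochondrion and one contact on a 160² px canvas (256² px for gaps
> 40 nm, so a 100 nm non-contact tubule still fits).

`degrade_mask` emulates segmentation error: each object is independently
dilated or eroded by a random radius up to the jitter parameter, then
labels within the jitter distance of class boundaries flip with a given
probability. With jitter 2 px a planned gap moves by at most ±4 px, enough
to flip contacts near the 15 nm boundary between types — which is why
total loose-contact length (a wide 15–80 nm band) correlates better with
its clean value across degraded scenes than total close-contact length
does. That ordering is asserted as a stochastic trend over a fixed set of
100 seeded scenes; with constant-gap contacts both correlations are high
(~0.95–0.98), so the margin between them is modest.

## Numerical choices

- Distance comparisons are float nm; no threshold is ever rounded to
  pixels internally.
- `nm_to_px` rounds half away from zero (80/0.38 = 210.53 → 211).
- Tie-breaks are deterministic everywhere: objects ordered by top-left-most
  pixel; contours start at the top-left-most boundary pixel, clockwise;
  contact segments ordered by first contour index; CSV rows sorted by
  image id. Identical inputs give byte-identical CSV.
- Conservation/monotonicity assertions use a 1e-9 nm slack for float
  summation; the distance-field oracle comparison uses 1e-9 nm absolute.
- The CSV prints lengths, areas and fractions with 3 decimals; the
  library returns full-precision floats.

## Problem sizes in tests

The default test run regenerates everything it needs: oracle comparisons
on 50 random masks ≤ 64², threshold recovery on 50 scenes per gap ×
8 gaps, robustness correlations on 100 scenes of 320² px, metric
identities on 100 random mask pairs — about half a minute in total on one
core. The acceptance script repeats the same computations from its own
seed.

## Known limitations

- 2-D sections only: contact counts and lengths depend on the sectioning
  plane; no attempt is made to infer 3-D contact architecture.
- One external contour per object: ER lumina or mitochondrial holes are
  ignored by design; a hole-aware mode is out of scope.
- Contacts are not paired with specific ER objects; a single run may face
  several tubules.
- The grid-cell estimator renormalizes in the (rare) case where per-class
  cell hits sum above 1, slightly compressing extreme estimates.
- `degrade_mask` applies object-wise morphology sequentially, so a dilated
  object never overwrites another organelle's pixels; heavily overlapping
  degradations are therefore order-dependent (mitochondria first).
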