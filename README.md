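# mercquant

Quantification of mitochondria–endoplasmic-reticulum contact sites (MERCs)
from calibrated segmentation masks of transmission electron micrographs.

MERCs — regions where the ER membrane approaches the outer mitochondrial
membrane to within roughly 10–80 nm — regulate calcium signalling, lipid
transfer and mitochondrial dynamics, and their frequency and extent shift
under drug treatment and disease. Measuring them from 2-D TEM sections
means segmenting the organelles and then doing careful geometry on the
segmentation masks. `mercquant` implements that second half: it takes a
three-class label mask (0 = background, 1 = mitochondria, 2 = ER) from
*any* segmenter — neural network or human annotator — and turns it into
contact-site statistics. It is aimed at cell biologists and image-analysis
engineers who already have masks and want reproducible numbers.

## Method

For each image the pipeline:

1. finds connected organelle objects and traces each object's external
   boundary as an ordered, closed pixel contour (Moore-neighbor tracing);
2. computes an exact Euclidean distance transform seeded at the ER contour
   pixels, giving every pixel its distance *d* (in nm, via the pixel
   calibration) to the nearest ER membrane;
3. classifies every mitochondrial contour pixel: **close** contact if
   *d* < 15 nm, **loose** contact if 15 ≤ *d* < 80 nm, otherwise free;
4. groups maximal contiguous runs of same-type contour pixels into contact
   segments, and reports per image the counts and total arc lengths of
   first-type (close) and second-type (loose) contacts —
   N<sub>C1</sub>, L<sub>C1</sub>, N<sub>C2</sub>, L<sub>C2</sub> —
   together with object counts, areas (nm²) and area fractions.

Arc lengths are polyline lengths through pixel centers (steps of 1 or √2
px × pixel size), so they are consistent under image rotation. Both
thresholds, the inequality convention and the grouping semantics are
configurable (`MercParams`).

Around this core the package provides: pixel-level segmentation scoring
(3×3 confusion matrix; per-class precision, recall, IoU/Jaccard, F1/Dice;
pooled over a dataset or averaged per image), a stereological grid-point
estimator of area fractions emulating manual grid counting, and a seeded
synthetic-scene generator that places elliptical mitochondria and thin ER
tubules at *planned, known gaps* so every stage can be validated offline
against analytic ground truth.

## Worked example

```bash
python examples/quantify_contacts.py
```

builds a 320×320 synthetic scene (1 nm/px) with one contact planned at a
10 nm gap and one at 30 nm, runs the detector and prints:

```
image: scene_42  (320x320 px, 1.0 nm/px)
mitochondria: 2  total area 7125 nm^2
ER objects:   3  total area 1637 nm^2
close contacts (N_C1): 1   total length (L_C1) 58.8 nm
loose contacts (N_C2): 2   total length (L_C2) 315.0 nm
total mitochondrial contour: 441.8 nm
```

The 10 nm tubule appears as the one close contact; the 30 nm tubule (and
a flanking stretch of the close contact's arc, which lies in the 15–80 nm
band) make up the loose contacts. L<sub>C1</sub> + L<sub>C2</sub> ≈ 374 nm
of the 442 nm mitochondrial boundary is engaged in contacts. The other
examples demonstrate segmentation scoring, ground-truth recovery across
gaps, and the bias of manual grid counting (`examples/*.py`).

From the shell, the same pipeline runs over directories of PNG/TIFF masks:

```bash
mercquant quantify masks/ --out report.csv --pixel-size-nm 0.38 \
    --close-nm 15 --loose-nm 80 --overlay-dir overlays/
mercquant eval truth_masks/ predicted_masks/ --out metrics.csv
mercquant synth scene.yaml out/
```

`quantify` writes one CSV row per image (counts, areas, contact lengths,
area fractions) and, on request, overlay PNGs with contours in magenta
(mitochondria) / turquoise (ER) and contact segments in blue (close) /
green (loose).

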