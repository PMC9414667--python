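# Methods

## The localization model

`shootpick` post-processes instance-segmentation output for robotic tea
harvesting.  Given a binary mask of one tender shoot, the picking point — the
stem location where the shoot should be severed — is derived purely
geometrically, in four steps:

1. **Main connected domain.**  Predicted masks can be fragmented (detached
   blobs, holes).  The mask is split into connected domains and the largest
   one is kept as the shoot's main body: picking points are more likely to
   lie in large connected domains, and fragments are usually segmentation
   noise.  Connectivity defaults to 8 (corner-adjacent pixels connect), which
   keeps thin diagonal stems in one piece; 4-connectivity is available.
   Area ties are broken by the lexicographically smallest (row, col) pixel so
   output is deterministic.
2. **Minimum circumscribed rectangle.**  The smallest-area oriented rectangle
   enclosing the main domain.  It is fitted to the convex hull of the pixel
   *unit-square corners*, not the pixel centers: this guarantees every pixel
   is fully covered and keeps tiny components (down to a single pixel)
   well-defined.  The rotating-calipers optimum is computed by shapely's
   `minimum_rotated_rectangle`.
3. **Shoot axis.**  The segment through the rectangle center, parallel to its
   long side and spanning it.  The endpoint further down the image is the
   *bottom* (shoots grow upward); for an exactly horizontal axis the
   larger-x endpoint is bottom, and for an exactly square rectangle the axis
   is declared vertical — both degenerate rules exist only to make output
   deterministic, and the square case logs a warning.
4. **Picking point.**  The point at `fraction` (default 0.02, i.e. 2%) of
   the axis length up from the bottom endpoint, with the axis inclination
   reported as the suggested knife angle θ.  The 2% rule reflects the
   empirical observation that the cut belongs just above the bottom of the
   masked region, below the stem/leaf intersection.  The point lies on the
   axis line and is not snapped to a mask pixel.

### Coordinate and angle conventions

Image coordinates are x = column (rightward), y = row (downward), origin at
the upper-left corner, 0-based; a pixel (r, c) is the unit square
[c, c+1) × [r, r+1), and a polygon covers a pixel iff it covers the pixel
center (boundary included).  Angles are degrees in [0, 180), measured from
the +x axis toward −y (upward on screen, i.e. visually counterclockwise);
a vertical shoot has θ = 90°.  θ is reported against the image horizontal —
equivalently the bottom edge of the axis-aligned detection box — not against
the oriented rectangle's own short edge (which would make it identically
90°).

## Evaluation metrics

**Shoot identification.**  Predictions are matched to ground truth greedily
in descending score order, one-to-one, at each threshold of an IoU grid
(default 0.50 to 0.95 in steps of 0.05).  `mAP` is the mean over the grid of
the point precision TP/(TP+FP) and `mAR` the mean point recall TP/(TP+FN);
no score-swept PR curve is integrated — the metric is a point measure at
each threshold by its defining formula.  The summary score is

    F_beta = (1 + beta) · mAP · mAR / (beta² · mAP + mAR),   beta = 2.

Note the (1 + beta) numerator: it differs from the textbook
(1 + beta²) F-measure, but it is the form the reference results were
computed with (it reproduces their printed F2 column exactly), so it is the
default; the textbook form is available via `standard=True`.  With beta = 2
this weights the sweep's precision above its recall, appropriate when the
picker images each bush from several angles and a missed shoot is
recoverable but a spurious cut is not.  Empty denominators (no predictions,
or no truths) define the ratio as 0 with a warning.

**Picking points.**  Predicted and true points are matched one-to-one,
greedily by ascending distance, within a tolerance (default 10 px at
1512×1008 resolution — no published definition of "correctly identified"
exists, so the tolerance is explicit and configurable).  Matched pairs are
ED, unmatched truths EN, unmatched predictions ND; precision = ED/(ED+ND),
recall = ED/(ED+EN).  Multi-image evaluations match per image and pool the
counts before computing the ratios (micro-averaging).

## Detector loss formulas

`rcnn_math` implements the two-stage detector's training math on plain
arrays: anchor labeling (IoU > 0.7 positive, < 0.3 negative, otherwise
excluded from training), greedy NMS at IoU > 0.7, smooth-L1 box regression
(summed over the 4 offset components), classification and per-pixel mask
binary cross-entropy, and the composite L = L_RPN + L_head with adjustable
λ₁, λ₂, γ (all default 1 — no published values exist) and per-term
normalizers.  The printed classification loss −p*·log p assigns zero loss to
negative samples, contradicting its own description as binary cross-entropy;
the full BCE is therefore the default and the truncated printed form is kept
behind `variant="printed"`.  Probabilities are clamped at ε = 1e−12 before
logs.  Network forward passes, anchor generation and RoI pooling are out of
scope.

## Synthetic shoots

No annotated tea-shoot dataset is publicly deposited, so correctness is
demonstrated on simulated masks with closed-form ground truth.  A shoot is a
**capsule**: a straight spine swept with a circular cross-section of radius
width/2, optionally widening toward the tip by a `bud_bulge` factor
(mimicking the bud) and carrying interior circular holes (`hole_rate`,
punched strictly inside so the body stays connected and retains ≥ 50% of
its area).  The truth axis runs tip-to-tip; the truth picking point applies
the same 2% rule, so capsule recovery is exact by construction up to
rasterization.

Scene defaults model close-up field photographs at 1512×1008 px: lengths
U(120, 260) px, widths U(12, 26) px, axis angles U(60°, 120°)
(near-vertical growth), and an `overlap_fraction` that forces that fraction
of shoots into overlapping pairs, emulating dense canopies.  `perturb`
degrades masks the way an imperfect segmenter would: boundary-pixel flips
(`boundary_noise`) and detached small fragments (`fragment_rate`, placed at
≥ 3 px clearance so they never merge with the main body).

What the generator does *not* emulate: curved stems, leaves and the
"one tip, two leaves" morphology, occlusion by mature foliage, illumination
and focus variation, and annotation subjectivity.  Passing recovery tests
therefore demonstrate the geometric pipeline's correctness on its own model
assumptions (elongated, straight, mostly vertical blobs), not field accuracy
of any segmentation network.

### An identifiability limit

For the symmetric capsule, the minimum-area rectangle's long axis coincides
with the spine, and the pipeline recovers the axis angle to ≈ 0.04° and the
picking point to ≈ 0.6 px (95th percentiles over 200 shoots).  With a
teardrop bulge the two quantities genuinely differ: the minimum rectangle of
an asymmetric teardrop tilts away from the spine by up to ~1.7° at
bulge = 0.3, moving the inferred picking point by ~3 px.  This is a property
of defining the axis through the minimum rectangle, not an implementation
error; the parameter-recovery suite therefore uses pure capsules
(`bud_bulge = 0`, the `ShootSpec` default), and bulged shoots appear in
scene generation and robustness tests instead.

## Numerical choices

- Rectangle side comparison uses a 1e−9 relative tolerance to detect exact
  squares; rectangle containment of pixel squares holds to 1e−6 px.
- File output rounds coordinates and angles to 2 decimals; memory keeps full
  precision.
- The IoU grid divisor is the grid length (10 by default); the grid is
  user-configurable.
- All randomness flows from a single integer seed per call through
  `numpy.random.default_rng`; no global state.
- Problem sizes in the test and acceptance suites (200 recovery shoots at
  full 1512×1008 resolution, 100 random convex blobs against a 0.01°
  orientation-sweep oracle, 200 random 32×32 masks against a BFS flood-fill
  oracle) were chosen to exercise the estimators well past their asymptotic
  regime while keeping the suite fast.

## Known limitations

- The axis model assumes a straight shoot; strongly curved shoots would need
  a medial-axis or skeleton model.
- Shoot length is defined as the rectangle long side (axis length), not a
  pixel count along the axis projection; for ragged masks the two differ.
- The LabelMe export writes the exterior ring only: masks with interior
  holes round-trip with the holes filled.
- The labeled-PNG scene export draws later instances on top, so overlapping
  regions lose the lower label; the polygon JSON is the lossless record.
- 2-D only: no depth or 3-D positioning of the cut.
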