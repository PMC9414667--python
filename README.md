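# shootpick

Picking-point localization from tea-shoot instance masks, with the matching
evaluation metrics.

Premium tea is picked as the tender "one tip, two leaves" shoot, and an
automated picker needs two things from a vision system: the contour of each
shoot (instance segmentation) and the point on the stem where the knife
should cut.  `shootpick` implements the geometric post-processing that turns
a segmented shoot into a cut instruction, plus everything needed to evaluate
such a system end-to-end:

- **`picking_geometry`** — from one binary mask: largest connected domain →
  minimum circumscribed rectangle → shoot axis and knife angle θ → picking
  point at 2% of the shoot length from the bottom of the axis.
- **`detection_eval`** — IoU (box and mask), greedy one-to-one matching over
  an IoU threshold grid (0.50:0.05:0.95), mAP/mAR as mean point
  precision/recall over the grid, and the summary score
  `F_β = (1+β)·mAP·mAR / (β²·mAP + mAR)` with β = 2 (note the (1+β)
  numerator; the textbook (1+β²) form is available behind a flag).
- **`picking_eval`** — ED/EN/ND point-matching tallies within a pixel
  tolerance; precision = ED/(ED+ND), recall = ED/(ED+EN).
- **`rcnn_math`** — reference implementations of the two-stage detector
  training math: anchor labeling (IoU 0.7/0.3), greedy NMS, smooth-L1,
  classification/mask cross-entropy, and L = L_RPN + L_head.
- **`synthetic_shoots`** — capsule-shaped shoot masks with closed-form axis,
  length and picking point, for testing without field data.
- **`io_formats` / CLI** — LabelMe-dialect polygon JSON, labeled PNG rasters,
  CSV + JSON result files; `shootpick` command with `locate`, `eval-det`,
  `eval-points`, `simulate` and `losses` subcommands.

See `docs/methods.md` for the model, conventions and known limits.

## Worked example

Simulate a scene of 5 shoots, locate their picking points from the emitted
annotation, and score the localization against the generator's truth:

```sh
$ shootpick simulate --n 5 --size 600x800 --seed 42 --out demo
$ shootpick locate --input demo/scene.json --out demo/pred.csv
$ head -4 demo/pred.csv
instance,x,y,theta_deg
0,543.54,267.17,110.82
1,325.43,556.54,87.34
2,394.68,264.96,73.02
$ shootpick eval-points --pred demo/pred.csv --truth demo/truth.csv --tolerance 10
{
 "ed": 5,
 "en": 0,
 "nd": 0,
 "tolerance_px": 10.0,
 "precision": 1.0,
 "recall": 1.0
}
```

Each row of `pred.csv` is one shoot: picking-point coordinates in pixels
from the image upper-left corner and the suggested knife angle in degrees
from the horizontal (90° = vertical shoot).  All 5 points fall within the
10 px tolerance of the true points (ED = 5, no misses EN, no spurious
detections ND), so precision and recall are both 1.0.

From Python, the same F2 summary used for shoot identification:

```python
>>> from shootpick import paper_f_beta
>>> round(paper_f_beta(0.449, 0.544, beta=2.0), 3)
0.313
```

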