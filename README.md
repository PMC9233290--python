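# fundustk

Toolkit for evaluating retinal-lesion segmentation and diabetic-retinopathy
(DR) grading pipelines on six-field-style fundus images. Because clinical
fundus datasets and trained CNNs cannot be redistributed, the package ships a
seeded synthetic generator so the entire pipeline — segmentation output,
component-level evaluation, inter-annotator agreement, tiled inference and
presegmentation-based grading — runs end-to-end on desk-scale data.

## What's inside

| module | purpose |
|---|---|
| `fundustk.labels` | fixed label set: background, optic disc, 7 lesion classes (MA, HEM, CWS, HE, PC, IRMA, NV) |
| `fundustk.synth` | seeded synthetic fundus images + masks, a simulated second annotator, corrupted "model output" masks, ICDR-consistent grades, NV-stratified patient-exclusive splits |
| `fundustk.detection` | component-level matching (one-pixel overlap), lesion- and image-level precision/recall/F1, adjusted (class-agnostic) precision, false-positive confusion tables |
| `fundustk.agreement` | per-image lesion counts and ICC(2,1) inter-annotator agreement |
| `fundustk.tiling` | sliding-window patch sampling, flip/shift/gamma augmentation, multi-head softmax fusion, overlapping-tile full-resolution inference with edge cropping |
| `fundustk.grading` | presegmentation preprocessing (border crop → color superimposition → area downsampling), rule-based ICDR grader, per-class accuracy, quadratic weighted kappa, macro one-vs-rest AUC |
| `fundustk.io` / `fundustk.cli` | indexed-PNG masks with a guarded palette, grade CSVs, YAML manifests, and the CLI |

Conventions: coordinates are 0-based `(row, col)` from the top-left; masks are
`uint8` with background = 0 and optic disc = 1; the seven lesion labels are
2–8 in the order MA, HEM, CWS, HE, PC, IRMA, NV, which is also the
deterministic tie-break order.

## CLI

```bash
# generate a 60-image synthetic dataset (images, reference masks, second
# annotator, corrupted model masks, grades, splits, manifest)
fundustk synthesize --out data/demo --n-images 60 --seed 1

# lesion- and image-level detection metrics + confusion tables
fundustk detect-eval --pred data/demo/masks_pred --ref data/demo/masks_ref --out reports/det

# per-class ICC between two annotators
fundustk agreement --masks-a data/demo/masks_ref --masks-b data/demo/masks_second --out reports/icc.csv

# overlapping-tile inference with the reference color-threshold segmenter
fundustk tile-predict --images data/demo/images --out data/demo/masks_tiled --tile 320 --margin 32

# classifier-input preprocessing (crop border, superimpose mask, resize)
fundustk preprocess --images data/demo/images --masks data/demo/masks_pred --out data/prep --size 598

# grading metrics from grade CSVs
fundustk grade-eval --pred-grades pred.csv --ref-grades data/demo/grades.csv --out reports/grading
```

All commands are deterministic given their options; manifests record a
configuration hash so runs can be reproduced exactly.

## Notes

- The synthetic generator is calibrated for topology and size statistics,
  not photorealism; all geometry scales with image size (default 640×640).
- `tiled_predict` is exactly equivalent to whole-image prediction for any
  pixelwise predictor — the test suite checks this property, which is what
  makes the edge-cropped stitching trustworthy.
- Training of full-scale neural segmentation/classification models is out of
  scope; the `Predictor` protocol documents the contract any backend must
  satisfy to plug into tiled inference.
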