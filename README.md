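# tonguelab

Color-space feature extraction and supervised classification for
tongue-image diagnosis experiments.

Every 8-bit RGB pixel is expanded into 25 normalized features spanning
eight color models (RGB, HSV, YIQ, Y'CbCr, XYZ, L\*a\*b\*, CIE Luv,
CMYK). Per-pixel features are aggregated over a region of interest —
the whole tongue foreground or a central rectangle of its bounding
box — with five statistics variants (mean, median, std, mean+std,
median+std; 25 or 50 components). The resulting vectors feed three
binary classifiers (boosted decision trees, an SMO-trained
polynomial-kernel SVM, a backprop MLP), evaluated by stratified 3-fold
cross-validation with classification accuracy and the class-size
weighted F-measure. Feature relevance is scored by information gain
over MDL-discretized features, and subsets are chosen by forward
best-first search with a correlation-based merit. A synthetic cohort
generator produces labeled elliptical tongue images (class-conditional
body and coating colors, Gaussian noise) so the entire pipeline runs
without any external data.

## CLI

The `tonguelab` entry point chains the whole protocol:

```bash
# synthetic labeled cohort (PNG images + masks + manifest.csv)
tonguelab simulate --out cohort/ --seed 1 --n-pos 132 --n-neg 68

# one aggregate feature row per image
tonguelab extract --manifest cohort/manifest.csv --out features.csv \
    --region entire --variant median_std

# cross-validated report for one classifier
tonguelab evaluate --features features.csv --classifier svm --out report.json

# train + serialize a model, rank features, select a subset
tonguelab train --features features.csv --classifier adaboost --model-out m.json
tonguelab rank --features features.csv --out ranking.csv
tonguelab select --features features.csv --out subset.csv

# full variant x classifier x region grid (config optional, YAML)
tonguelab experiment --manifest cohort/manifest.csv --out grid.csv --comparison
```

Masks are single-channel PNGs (0 = background); when absent, the whole
image is treated as foreground. For synthetic images the mask equals
"not the fixed background color".

## Package layout

- `tonguelab.colorspace` — 25-feature per-pixel extractor and constants
- `tonguelab.region` — foreground bounding box and middle-rectangle regions
- `tonguelab.aggregate` — the five aggregation variants
- `tonguelab.classify` — AdaBoost (+ weighted trees), SMO SVM, MLP
- `tonguelab.evaluate` — confusion counts, weighted F, stratified CV
- `tonguelab.featsel` — MDL discretization, information gain, best-first
- `tonguelab.simulate` — synthetic cohort generator
- `tonguelab.pipeline` / `tonguelab.cli` — experiment orchestration and CLI
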