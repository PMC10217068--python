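# fundushybrid

A hybrid feature pipeline for classifying colour fundus photographs into
four classes (cataract, diabetic retinopathy, glaucoma, normal). The
package implements:

- **Enhancement** — 5×5 centre-excluded averaging, Laplacian edge response,
  and their sharpening combination, plus filter-quality metrics (MSE,
  edge-preservation index, structural content).
- **Handcrafted features** — a fixed 255-dimensional descriptor per image:
  24 GLCM texture statistics (6 statistics × 4 directions), a 16-bin fuzzy
  colour histogram over hue, a 203-bin histogram of 24-bit local binary
  codes from 5×5 neighbourhoods, and 12 one-level Haar wavelet sub-band
  statistics.
- **Deep features** — a pluggable backbone adapter producing N×2048
  matrices. The bundled deterministic "toy" backbone (patch-grid average
  pooling + fixed random projection) needs no downloads; pretrained specs
  fail loudly when weights are unavailable.
- **PCA + fusion** — reduction to 450 components per model and the three
  fusion pathways with exact width contracts: concat-then-PCA (4096 → 710),
  PCA-then-concat (450 + 450 = 900), and CNN + handcrafted (450 + 255 = 705).
- **Dataset plumbing** — class-per-folder image I/O, the two-stage 80/20
  split (e.g. a class of 1038 images → 664 train / 166 validation /
  208 test), 9-fold training augmentation (flips, rotations, shifts), and a
  fully seeded synthetic fundus generator with class-conditioned effects.
- **Classifier + evaluation** — a softmax network (one hidden layer of 15
  units by default) trained with momentum gradient descent, validation-
  patience early stopping and gradient-floor stopping; confusion matrices,
  one-vs-rest percentage metrics, ROC AUC, per-phase error histograms and
  full training traces.

## CLI

```bash
fundushybrid synth    --out data/ --n-per-class 100 --seed 0
fundushybrid enhance  --in data/ --out enhanced/
fundushybrid features --in enhanced/ --out features.csv --set handcrafted
fundushybrid split    --in data/ --out split.csv --seed 0
fundushybrid augment  --in data/ --out augmented/
fundushybrid run      --strategy s3_mobilenet_hand --seed 0 --out runs/s3
```

`run` executes one of six strategies end-to-end (enhance → split →
features → PCA/fusion → train → evaluate) and writes `split.csv`,
`confusion.csv`, `metrics.json` and `trace.csv` to the output directory.
Without `--in` it runs on the synthetic dataset.

Strategies: `s1_mobilenet`, `s1_densenet` (single backbone + PCA),
`s2_fuse_before`, `s2_fuse_after` (two backbones fused before/after PCA),
`s3_mobilenet_hand`, `s3_densenet_hand` (backbone PCA block + handcrafted).

## Notes

- On toy-sized datasets, PCA component counts are capped at `N − 1`; the
  cap is logged, never silent.
- Everything stochastic is seeded: the synthetic generator, splits, network
  initialisation. Identical config + seed ⇒ bit-identical outputs.
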