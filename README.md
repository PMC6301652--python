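# penyek

An automated pipeline for classifying damaged ("flattened") brown
planthopper (BPH) insects versus benign insects in sticky-pad trap
images. The pipeline chains:

1. **Binarization front end** (`penyek.preproc`) — grayscale conversion,
   median filtering, iterative two-threshold binarization by
   between-class-variance maximization, morphological closing/opening
   and size filtering, plus patch extraction and Canny-based negative
   patch mining.
2. **Binary image models A–G** (`penyek.bintrans`) — outline, fill
   holes, skeletonize, binary watershed separation, Voronoi ridges, the
   **Euclidean Distance Map** (the best-performing model, F), and a raw
   RGB passthrough (G).
3. **CNN classifier** (`penyek.cnn`) — a pure-NumPy network engine with
   hand-rolled backprop (no deep-learning framework needed), seven
   small architecture presets, a VGG16-style architecture with
   fine-tuning controls (truncated 2-class head, frozen early blocks,
   reduced learning rate), seeded rotation/translation augmentation,
   training, prediction and hard-negative bootstrapping.
4. **Hand-crafted baselines** (`penyek.baselines`) — GLCM, Gabor, LBP
   and gray/HSV/RGB histogram features with a seeded random forest.
5. **Evaluation** (`penyek.evaluate`) — stratified 5-fold CV, accuracy /
   sensitivity / specificity and Mann-Whitney AUC.

Because no public sticky-pad dataset exists, `penyek.imgen` generates
fully seeded synthetic scenes: procedural two-class insect sprites with
configurable damage (boundary-sector removal + shear), glue specks, a
multiplicative illumination ramp and sensor noise, with ground-truth
bounding circles. Every downstream stage is developed and tested
against this generator.

## CLI

```bash
# render 3 synthetic pad scenes + ground-truth circle annotations
penyek simulate --out scenes/ --seed 1 --n-scenes 3

# crop labelled patches from the annotation circles
penyek preprocess --images scenes/ --annotations scenes/annotations.csv \
    --out patches/ --patch-size 49

# apply an image model (F = Euclidean Distance Map)
penyek transform --model F --in patches/ --out edm/

# train / score a CNN structure preset
penyek train --in edm/ --structure 5 --batch 30 --lr 0.0001 --epochs 30 \
    --seed 1 --augment both --out model
penyek predict --weights model --in edm/ --out preds.csv

# cross-validate a texture baseline or a CNN arm
penyek baseline --scheme RGB_hist --in patches/ --out rf.csv
penyek evaluate --arm edm_structure5 --in edm/ --out cnn.csv

# full seeded pipeline from a YAML config (defaults = small demo)
penyek run --config cfg.yaml --out rundir/ --seed 1
```

`penyek run` validates its config (unknown keys are rejected), echoes
the fully-defaulted config into the run directory, and is byte-for-byte
reproducible for a fixed config + seed.

## Acceptance

Acceptance is property-based (see `tests/test_acceptance.py`): exact
distance-map and thresholding optimality against brute-force oracles,
morphology contracts, convolution-layer equivalence with the reference
convolution, end-to-end learnability of the EDM + CNN arm on the
synthetic benchmark, the augmentation ablation ordering, baseline
ordering, metric identities, architecture-table fidelity and run
determinism. The published headline accuracies were measured on a
private dataset that was never deposited, so there are no recomputable
numeric targets; accordingly

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

writes an empty JSON object after a package self-check.
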