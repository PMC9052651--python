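# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish.

## Pipeline model

The pipeline classifies 256×256 immunohistochemistry crops into three
non-exclusive amyloid-beta classes (cored plaque, diffuse plaque, CAA).

**Preprocessing.** Slide rasters are color-normalized by Reinhard statistics
transfer: pixels are mapped RGB → LMS → log10 → lαβ with the standard
Ruderman matrices, standardized per channel, rescaled to the reference
channel standard deviations and shifted to the reference means. Channels
with near-zero spread are shifted but not scaled (scale guard 1), so
constant images map to the reference mean rather than dividing by zero.
Normalization is idempotent up to 8-bit quantization. Normalized rasters are
tiled into non-overlapping 1536×1536 tiles anchored at the origin; remainder
rows/columns are discarded. Candidate deposits are connected components of a
stain-specific HSV-range mask (H on 0–179, S and V on 0–255 — the only scale
on which the configured ranges, e.g. S up to 255, are meaningful). The mask
is smoothed with a Gaussian (σ = 2, 9×9 support) and re-thresholded at 0.5
before labeling, and components under 100 px (configurable) are dropped;
both values are exposed in configuration because speck suppression has no
single canonical setting. Detection runs on normalized color by default
(normalization precedes detection in the pipeline order), with a flag to
detect on raw color. Crops are 256×256 windows centered on component
centroids; windows that would cross a tile edge slide inward rather than
zero-pad, keeping photometric statistics natural for the CNN.

**Labels.** Each annotator's bounding-box marks become a per-image, per-class
floating-point value: the sum over positively marked boxes of the fraction
of the box's area inside the image window (box area is the denominator — the
value measures how much of each marked deposit the image contains). The
value is ≥ 0 and can exceed 1; the binary label is value > 0.99 (strict).
Auxiliary marks ("negative", "flag", "not sure") are stored for audit but
never affect labels — a class mark always wins, even alongside a "negative".
Consensus-of-n marks an image positive when at least n member tables are
positive; n = 1 is the union (maximal sensitivity), n = |members| the
intersection (maximal precision). Training sets are class-balanced by
replication: r1 = round(diffuse/cored), r2 = round(diffuse/CAA), both
floored at 1; cored-positive images are repeated r1 times, CAA-positive r2
times, and images positive for both minority classes max(r1, r2) times — the
max rule avoids compounding two replications on one image. Balancing is
recomputed on each training fold.

**CNN.** Six blocks of conv 3×3 (pad 1) → batch-norm → ReLU → maxpool 2×2
(stride 2), with filters 16, 32, 48, 64, 80, 96; a 256×256 input reaches a
4×4×96 = 1536-feature map and a single affine head emits three logits. The
sigmoid is applied at evaluation only. Training: Adam with learning rate
0.001 and weight decay 0.03 (L2 folded into the gradient), multi-label
soft-margin (per-class binary cross-entropy with logits) loss, 60 epochs,
batches shuffled from a named substream of the run seed. The checkpoint kept
is the epoch with the highest validation AUPRC on the cored class — the
scarce class the study protocol optimizes for — with the earliest epoch kept
on exact ties for determinism. Augmentation (training only): random
horizontal and vertical flips, 180° rotation with probability 0.5 (composed
with the flips this spans the dihedral group), color jitter of 0.1 in
brightness/contrast/saturation, and a random affine of ±10°, ≤5%
translation, 0.95–1.05 scale. The jitter and affine magnitudes are mild
defaults and configurable, as no canonical values exist. Evaluation applies
zero-mean/unit-variance normalization only, with channel statistics computed
from each fold's training split to avoid leakage. Splits are made at the
slide level: all crops from one slide share a fold, and hold-out test slides
contribute no training crops.

The engine is a compact numpy implementation (im2col convolutions, explicit
backward passes, float32 throughout); with a fixed seed, training is
bit-reproducible on CPU, and the parameter count is a closed-form function
of the architecture spec used as a test oracle.

**Ensembles.** M trained CNNs are linked by a sparse affine layer and
frozen; only the affine parameters train. The layer is block-diagonal per
class: ensemble logit c = b[c] + Σ_m w[m,c]·s[m,c], where s are the
constituents' post-sigmoid class scores — 3·(M+1) parameters. Two open
readings existed: full 3M→3 connectivity, and whether constituent scores
enter pre- or post-sigmoid. The block-diagonal, post-sigmoid reading was
chosen because the layer is described as weighting each constituent's final
class output; the fit is then convex in the trainable parameters. Weights
initialize at 1/M with zero bias (simple vote averaging) and train with the
same recipe as the CNNs (Adam, lr 0.001, wd 0.03, 60 epochs). Random-labeler
constituents are built from prevalence-matched label permutations: per
class, the positive count is the rounded mean of the expert counts and
positions are a seeded permutation, giving chance-level agreement with every
expert.

**Evaluation.** AUPRC is threshold-grouped average precision: tied scores
form one group and every example in it takes the precision at the group
boundary, so constant scores score exactly the class prevalence (the
metric's random baseline). AUROC is the Mann–Whitney statistic over P·N
pairs with half-credit ties. Cohen's kappa uses marginal-product expected
agreement; two constant, identical raters are defined as κ = 1. The four
benchmark schemes pair each model (5 expert-trained, 5 consensus-trained,
4 folds each) with its own benchmark (self), all five consensus tables
(consensus), all five expert tables (individual), or all ten (all), giving
per-side samples of 20/100/100/200 AUPRC values; consensus superiority is a
one-sided two-sample Z-test with sample (n−1) standard deviations.
Intra-rater consistency over a 4-replicate set (one first-phase plus three
second-phase presentations) is the modal-label fraction per class, averaged
over sets; agreement-with-first-phase is a plausible alternative reading and
is available by assembling the sets differently.

**Saliency.** Guided Grad-CAM: guided backpropagation (ReLU gradients gated
on positive activation and positive upstream gradient) multiplied by the
upsampled, ReLU'd class-activation map from the last convolutional block
(channel weights = spatially averaged gradients). Maps are min–max rescaled
to 0–255 before thresholding; the rescaling convention and the threshold
grid are not canonical, so thresholds default to 0–256 in steps of 8.
Binarization is ≥ t → 255. SSIM uses a 7×7 window with data range 255; two
identical constant maps (e.g. both empty at t = 256) score 1. Subset
fractions are |A∩B|/|A| with an empty ON-set defined as fraction 1 (vacuous
containment, avoiding 0/0).

**Phase-two protocol.** Self-repeat: all of an annotator's CAA positives,
random cored positives to 400, random diffuse positives to 600, duplicates
forbidden, shortfalls taken as available; the 600 are triplicated with
random quarter-turn rotations and shuffled (1800). Consensus-repeat: 250
random consensus-of-two positives per class, deduplicated across classes,
triplicated and shuffled. Self-enrichment: from the unseen pool, 800 random
images with cored score > 0.90 plus the top 800 by CAA confidence, expanded
with every neighbor sharing ≥ 20% of a plaque box's area with both crop
windows, shuffled, truncated to 3000. Consensus-enrichment: 750 random
predicted-positives per minority class (predicted positive = sigmoid score
> 0.5; the protocol names no threshold, so the conventional one is used),
topped up with random neighbors to 3476 — a protocol constant, not a derived
quantity. Images qualifying for both enrichment sets are assigned by a fair
per-image coin from a seeded stream. Enrichment uses the fold-three models
by default (the fold selected for this purpose in the study protocol),
configurable; the enrichment builder accepts any score table, so a
protocol-arithmetic run does not require trained weights.

## Synthetic data

The generator renders deposits on a neutral near-white background (exactly
gray, saturation 0, hence always outside every stain's HSV range) with
colors sampled inside the active stain's detection range, so the detector is
exercised by construction. Morphologies: cored = filled disk with a darker
core; diffuse = connected cloud of overlapping blobs with speckle holes,
lighter color; CAA = annulus with a clear lumen. Multi-class crops are drawn
as concentric, touching composites so each crop yields exactly one detected
candidate. Crops are produced through the real pipeline (render tile →
detect → center-crop → float labels from the rendered truth boxes). Default
prevalences are 12% cored / 88% diffuse / 2% CAA — the candidate-level class
distribution of the phase-one cohort — with cored/diffuse partitioning the
cohort and CAA overlaid on a random 2%, so realized counts hit targets
within rounding. Simulated annotators flip each truth label independently
per class and image (miss probability 1 − sensitivity, false-positive
probability 1 − specificity); the default cohort is five annotators at
sensitivity = specificity = 0.9.

What the synthetic fixtures do **not** emulate: chromogen chemistry and
tissue texture, focus and scanner artifacts, and — most importantly —
*correlated* annotator disagreement driven by genuinely ambiguous
morphology. Independent errors are the regime in which consensus voting is
provably beneficial; passing tests therefore demonstrate that the machinery
is correct and that consensus helps under independent noise, not that it
must help on any real cohort. A correlated-error profile can be added via
custom AnnotatorProfile seeds sharing flip decisions, and the tiny rendering
scale (below) trades visual fidelity for CPU tractability.

## Problem sizes and numerical choices

The test suite and the acceptance script run on one CPU, so sizes are scaled
down deliberately while keeping the stated study conditions where they
matter:

* The `tiny` profile uses 64×64 crops and a two-block CNN (filters 16, 32);
  the full 256×256 six-block path is the default for real data and its
  shape/parameter contracts are tested directly.
* The ensemble robustness experiment uses the study cohort — 2,000 tiny
  crops, five experts at 0.9/0.9 — with constituent CNNs trained for 5
  epochs at batch 64 (enough to separate the three morphologies on rendered
  data) while the affine ensembles train the full 60 epochs, since the
  ensembles are what the claim is about. Slide-level splitting uses 80 crops
  per synthetic slide, 33% hold-out.
* Metric guards: ranking metrics raise on single-class label vectors and
  such cells are skipped (never imputed) when averaging across benchmarks;
  the Z-test returns p ∈ {0, 0.5, 1} for zero-variance degenerate samples.
* All randomness flows from one seed through named, CRC-keyed substreams, so
  any stage can be re-run in isolation bit-identically.

## Known limitations

* The numpy CNN engine is single-threaded and unsuitable for slide-scale
  training; it exists for exactness, portability and testability.
* Pyramidal slide formats are out of scope; inputs are pre-exported RGB
  rasters.
* Probabilistic annotator models (e.g. Dawid–Skene) are deliberately not
  implemented; consensus-of-n is the object of study.
* Deposited-data statistics (agreement fractions, kappa matrices) are
  implemented and unit-tested on synthetic tables, but reproducing the
  published numbers requires the public data deposit, which is not bundled.
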