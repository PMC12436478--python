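# Methods

## Overview

`echostrain` implements a three-stage framework for predicting atrial
high-rate episodes (AHREs, device-detected subclinical atrial fibrillation)
from apical four-chamber (4CH) echocardiography:

1. **Segmentation** — an encoder–decoder network labels each frame into
   background, LA cavity and LA wall.
2. **Strain extraction** — the LA endocardial border is the sub-pixel 0.5
   iso-contour of the cavity label; its perimeter `L_t` yields the reservoir
   strain `(L_t − L_0)/L_0` with `L_0` taken at the base frame (the ECG
   R peak, i.e. LV end-diastole). Curves are resampled to 30 equidistant
   frames; peak strain is the curve maximum.
3. **Classification** — a transformer encoder attends over the 30 strain
   samples together with a summary token projected from ten clinical
   features (age, sex, BMI, BSA, CHA2DS2-VASc, MI, CAD, thyroid disease,
   DM, HTN) and outputs the probability that the longest AHRE reaches a
   6-minute or 24-hour threshold.

Because real cine loops and device interrogations are private clinical
data, the package validates each stage on synthetic inputs whose ground
truth is known analytically (phantoms) or by construction (cohorts).

## Synthetic phantoms

A phantom frame is a fan-shaped speckle sector containing two dark blood
pools: an LV-like ellipse near the probe and, below it, the LA. The LA
cavity is a truncated superellipse (exponent 2.5, flat chord at the
annulus side). Per frame the base contour is scaled isotropically about
the LA centre by a raised-cosine reservoir curve `s(t)` with `s = 1` at
frame 0 (the designated R peak) and peak `s_max` mid-sequence, normalised
so the peak is attained exactly at a frame. Isotropic scaling multiplies
the contour length by exactly `s(t)`, so the true strain `s(t) − 1` is
known in closed form and the whole mask→strain path can be checked
against it.

Texture: tissue and wall carry multiplicative exponential speckle
(levels 0.55 and 0.85), blood pools are dark Gaussians (0.15 ± 0.03), and
the image is blurred with a σ = 0.6 px Gaussian. This is deliberately
cheap — no wave propagation, shadowing, or probe-dependent point-spread —
but it is sufficient to make segmentation non-trivial (speckle, fuzzy
boundaries, a confusable second chamber). Consequences: passing the
scaled-down segmentation experiment shows that the architecture, loss,
augmentation and training loop work end to end; it does not certify
performance on clinical image quality, reverberation artifacts or
atypical anatomy.

Degenerate fixtures reproduce the five image-quality exclusion criteria
used when curating segmentation training data: (a) single-chamber scenes
(LV omitted), (b) masks clipped flat against the bottom image row,
(c) masks extending beyond the scan sector (sector radius shrunk so
≥ 5% of mask pixels fall outside), (d) blurred LA boundaries (σ = 6 px),
and (e) a black blob (intensity 0.01) covering ≥ 14% of the cavity.
Fixtures are constructed, not mined, and each violates exactly its own
criterion so the QC checks can be scored with clean labels.

## QC checks

Each criterion is a measurable proxy with a configurable threshold:
(a) absence of a second dark connected region ≥ 25% of the cavity area
inside the sector support (support = intensity > 0.02, closed and
hole-filled); (b) a run of ≥ 20 mask pixels on the last image row;
(c) ≥ 2% of mask pixels outside the sector support; (d) mean image
gradient along the cavity contour below half the dataset median;
(e) a connected sub-0.05-intensity blob inside the mask covering ≥ 10% of
the cavity (scattered dark speckle does not trigger it, and the normal
blood pool sits above the black level). The original curation was visual;
these proxies trade fidelity to individual human judgements for exact
reproducibility. Checks b/c/e are essentially geometric and detect their
fixtures perfectly; a/d are heuristics and are only required to reach 0.8
sensitivity/specificity. QC is applied only to segmentation training
data; strain and classification consume full sequences, since temporal
continuity matters there.

## Segmentation

Four architectures share one contract (1-channel frame in, 3-class logit
map out): ResUNet++ (pre-activation residual blocks with
squeeze–excitation, an ASPP bridge with dilations 1/2/4, attention-gated
skips), a group-normalised UNet, a UNet with a VGG-style plain
convolution encoder, and a DeepLab-like dilated model. The published
description fixes none of the depths/widths, so they are config knobs
with small defaults (base 8 channels, two poolings) chosen so CPU
training is feasible; VGG16 pretraining is not used.

Loss is soft Dice (ε = 10⁻⁶) plus cross-entropy over the 3-class softmax;
a 3-class formulation was chosen over two binary heads because cavity and
wall Dice are reported separately. Augmentation applies one shared
geometric transform to image and mask: rotation uniform in ±15° (range
not specified upstream; configurable) and a random crop whose *area*
fraction is uniform in (0.6, 1.0), resized back to the input size with
nearest-neighbour resampling for masks. Optimiser is Adam (unstated
upstream), batch 8, learning rate 10⁻³ under cosine annealing to ~0.

The networks run on a small in-package reverse-mode autodiff engine over
numpy (`echostrain.nn`): stride-1 im2col convolution with dilation,
max-pooling, nearest-neighbour upsampling, group/layer normalisation,
and the attention primitives. Every primitive's gradient is verified
against central finite differences in the test suite. Parameters and
activations are float64; at these model sizes numerical robustness costs
little.

**Scaled-down study conditions.** The reference experiment trains the
ResUNet++ variant on 200 phantom frames at 64×64 for 20 epochs and
evaluates on 50 held-out frames — sizes chosen so the full suite runs on
a single desk-grade CPU core. It is expected to reach cavity DSC ≥ 0.85
and wall DSC ≥ 0.60, preserving the cavity > wall ordering seen on real
data (thin wall, lower contrast). Training is deterministic given the
config seed.

## Strain extraction

Contours are extracted by marching squares at level 0.5 on the binary
cavity field of the largest connected component, after smoothing with a
σ = 1 px Gaussian: raw binary marching squares follows the pixel
staircase and biases the perimeter upward, while the smoothed field
crosses 0.5 near the true sub-pixel border (a rasterised r = 50 px disc
measures within 0.5% of 2πr). The closed perimeter includes the
annulus-side chord; whether expert tracing excluded the annulus plane is
unknown, and since strain is a length *ratio*, a consistently included
chord largely cancels. No temporal smoothing is applied by default; a
3-frame median filter over lengths is available behind a flag.

The base frame is the recorded R-peak index when present, else the
frame of minimum contour length (the LA is smallest at LV end-diastole),
ties resolving to the earliest frame. Resampling picks indices
`round(i·(T−1)/29)`, always keeping the first and last frames; sequences
shorter than 30 frames are rejected with an explicit error, mirroring the
acknowledged fixed-length limitation of the upstream design. Strains are
fractions everywhere in memory; percent appears only in summaries.

## Synthetic cohorts

`simulate_cohort` draws patients from a three-group mixture over AHRE
duration (< 6 min, 6 min–24 h, ≥ 24 h) with default probabilities
64/117, 40/117, 13/117 and per-group marginals set to the published
baseline characteristics of the 117-patient CIED cohort: age, BMI,
CHA2DS2-VASc and LA peak strain as truncated Gaussians (peak strain
31.1 ± 11.0%, 27.2 ± 8.3%, 19.9 ± 9.0% per group), binary features as
Bernoulli at the per-group prevalence. The published table has no BSA or
MI/CAD rows, so BSA is Normal(1.7, 0.2) m² and MI/CAD prevalences are
folded from the vascular-disease row (MI at half the vascular rate) —
documented placeholders, overridable via `CohortSpec`. AHRE duration is
log-uniform within the group interval (burden is heavily right-skewed,
so a flat-in-log duration is the natural minimal model); burden itself is
a clipped Gaussian. The CHA2DS2-VASc score is sampled independently per
group rather than recomputed from the simulated comorbidities — the
coherence of score components was not specifiable from the published
marginals.

A patient's 30-point strain curve rises from 0 at the base frame to
exactly the patient's peak strain mid-curve and relaxes to a plateau at
~55% of peak, with clipped additive noise so the maximum stays exact.
What the generator does *not* model: correlations among comorbidities
beyond group conditioning, medications, frame-rate variability, or any
direct mechanistic link between imaging and the tabular features — so
classifier experiments demonstrate parameter recovery under the stated
group-wise effect, not clinical transportability.

## Classifier

Transformer hyperparameters are wholly unstated upstream; defaults are
2 encoder layers, 4 heads, width 64, sinusoidal positional encoding,
dropout 0.1, Adam, batch 32, 400 epochs at lr 10⁻³ with cosine
annealing. Feature fusion is a learned summary token: the 10 standardised
features are projected to one token prepended to the 30 embedded strain
steps, and the token's final state feeds the sigmoid head — this keeps
self-attention over the strain sequence primary. Standardisation
constants travel in the checkpoint. Class imbalance is handled by
weighted BCE with `w_pos = negatives/positives` computed from the
training labels (the 24-h endpoint of the reference cohort gives exactly
104/13 = 8).

**Scaled-down recovery experiment.** n = 600 patients drawn with the
default group strain means but SDs halved; 24-h labels; stratified
fivefold CV with a width-32, 25-epoch, dropout-0.2 configuration (sized
for CPU minutes and chosen to keep the label-permuted null control near
chance — long training at this n memorises permuted labels and pushes
null CV-AUC visibly below 0.5 through the train/test anti-correlation
that permutation induces under cross-validation). Expected: mean CV-AUC
≥ 0.85 with the effect present, and within [0.35, 0.65] with labels
permuted.

## Evaluation statistics

Dice is 2|P∩T|/(|P|+|T|) per class (defined as 1 when both masks are
empty). Bland–Altman uses sample (n−1) SD and 1.96·SD limits. AUC and
ROC curves come from scikit-learn; tests assert exact agreement with a
brute-force Mann-Whitney U oracle (ties counted ½) to 10⁻¹². The Youden
operating point maximises sensitivity + specificity − 1 over midpoints of
consecutive sorted unique scores (± one threshold beyond each extreme),
ties resolving to the lowest threshold; accuracy is reported at that
threshold. Stratified fivefold CV uses scikit-learn's seeded
StratifiedKFold. Model comparison uses a two-sided independent t-test —
Welch by default (robust to unequal variances) with a flag for the
pooled-variance variant; per-image DSC values are the units of
comparison. Degenerate identical-sample input returns (t = 0, p = 1).

## Pipeline

`run_pipeline` executes simulate → QC → train-seg → segment → strain →
simulate-cohort → train-clf → evaluate, with patient-level stratified
80/(80/20)/20 splitting so no sequence crosses splits. One global seed
fans out to per-stage seeds through SHA-256 (`derive_seed`), so any stage
can be reproduced in isolation; a manifest records the config hash and
all stage seeds. The demo configuration (12 sequences of 30 frames at
64 px, 5 segmentation epochs, a 300-patient cohort with a 30-epoch
classifier) is sized to complete in a few minutes on one CPU while still
exercising every stage; segmentation inference and strain extraction are
deterministic, so a resumed re-run reproduces the strain table
byte-for-byte.

## Known limitations

- The phantom is a geometric scene, not an acoustic simulation; absolute
  DSC/strain figures on phantoms do not transfer to clinical data.
- Only global (not six-segment regional) strain is computed.
- Sequences with fewer than 30 frames are rejected rather than
  interpolated.
- The cohort simulator reproduces marginals, not joint structure; CHA2DS2-VASc
  is not internally consistent with its component comorbidities.
- UNet16 trains from scratch; without VGG pretraining it is the weakest
  of the four segmenters at these sizes.
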