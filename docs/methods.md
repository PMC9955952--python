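# Methods

## Problem and model

`piradscaps` jointly segments prostate lesions and grades them on
multiparametric MRI (mpMRI). Each case supplies three aligned volumes —
T2-weighted, ADC, and a zonal mask separating transition zone (TZ) from
peripheral zone (PZ) — and the model processes the case slice by slice
with a shared 2-D network:

1. **Ordinal segmentation.** PI-RADS categories (1/2 grouped, 3, 4, 5)
   are encoded cumulatively: bit *k* of a 4-bit vector means
   "class ≥ k". Ground-truth label maps become four nested binary
   channels, and the decoder predicts the four channels with independent
   sigmoids plus a fifth channel for benign (BPH) nodules. Unlike
   one-hot training, adjacent grades share supervision, so the grade
   progression is part of the signal. Predicted vectors may be
   non-monotone at inference; decoding takes the length of the *leading*
   run of supra-threshold bits, which never upgrades a lesion past the
   first unconfident bit.
2. **Capsule grade branch.** The encoder's deepest features
   (6×6×256 at the default width) are reshaped into a grid of 32 capsule
   types × 8 dimensions, squashed so every vector norm lies in [0, 1).
   A second capsule layer with routing-by-agreement (3 iterations)
   terminates in two class capsules whose lengths score low grade
   (PI-RADS 1/2/3) versus high grade (PI-RADS 4/5). Three fully
   connected layers reconstruct the encoder features from the winning
   capsule (ground-truth capsule during training); the sigmoid of the
   reconstruction gates the encoder features entering the decoder, so
   the segmentation attends to grade-relevant structure.
3. **Inter-slice recurrence.** A convolutional GRU runs over the
   capsule feature stack from base to apex, `h_s = Φ(h_{s−1}, e_s)`,
   with state shape equal to input shape. It sits between the two
   capsule layers; an ablation flag (`gru_enabled=False`) removes it.

### Loss

`L = 0.5·dice + 0.5·BCE + margin + 0.0005·MSE`. Dice and BCE average
over the five sigmoid channels (averaging rather than summing keeps the
decoder loss on the same scale regardless of channel count). The margin
loss uses the standard capsule constants m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 and
is applied only on lesion-bearing slices — empty slices carry no grade.
The reconstruction MSE compares against the encoder features with the
gradient stopped on the target side, so the encoder cannot shrink its
own features to please the reconstruction; "masked" refers to the
single-capsule masking, not a spatial mask.

### Architecture choices

The backbone is a lightweight four-stage encoder of depthwise-separable
blocks (stride-2, kernel-4 downsampling + kernel-3 refinement; widths
32/64/128/256) chosen so a 100×100 crop maps exactly to 6×6 spatial
features, with a mirrored skip-connected decoder using nearest-neighbour
upsampling. Routing iterations (3) and class-capsule dimension (16) are
the canonical capsule-network defaults. The GRU gates use 3×3
convolutions. At inference the reconstruction masks by the longest
capsule.

## Numerical engine

No deep-learning framework is used: the model runs on a small in-package
reverse-mode autodiff engine over float32 NumPy arrays
(`piradscaps.autodiff`). Convolutions are computed as shift-and-add over
the k² kernel taps, each tap a BLAS GEMM, which keeps memory flat and is
fast enough to train the desk profile on one CPU core. All operator
gradients are verified against central finite differences in the test
suite, and the routing implementation against a straight-line loop
oracle. Optimization is Adam (β = 0.9/0.999, ε = 1e−8) with the step
schedule `lr = 0.002 · 0.8^⌊epoch/20⌋` ("every 20 steps" is read as
every 20 epochs; per-iteration decay would extinguish the rate almost
immediately at a 300-epoch budget). Gradients are clipped to a global
L2 norm of 5 — unclipped runs occasionally destabilized late in
training once the dice term saturates. BCE probabilities are clamped at
1e−7; dice uses ε = 1e−6; squash guards the norm with ε = 1e−8.

## Batch semantics

The recurrence needs case-contiguous ordered slices, so one optimizer
step processes one case's whole slice sequence (9–14 slices).
`batch_size` is kept as the nominal slice-batch count and maps to
`ceil(batch_size / mean slices per case)` cases per step — one case per
step at the desk default of 8. Augmentation (shift ±10 px, scale
0.9–1.1, horizontal flip at p = 0.5) samples **one** transform per case
and applies it to every slice and mask alike, preserving the spatial
alignment the GRU depends on; validation data always bypasses
augmentation. Checkpoint selection uses validation dice when a
validation set is given.

## Synthetic phantoms

The phantom generator emulates the structure of a clinical prostate
mpMRI cohort: 9–14 slices per case, 0.68 mm/px in-plane T2 grid with the
ADC rendered through a coarser 1.17 mm/px grid before alignment, lesion
class frequencies 14/28/34/24 % over PI-RADS 2–5, 1–3 lesions per case
(70 % PZ), and benign TZ nodules in 70 % of cases (clinical cohorts
average about two nodules per patient). Geometry is a two-tissue
ellipsoid model (prostate + anterior inner TZ ellipsoid); lesions are
smoothed ellipsoidal blobs whose T2/ADC signal drop and size grow with
PI-RADS class (T2 drop 18→55 %, ADC drop 25→68 % from class 1 to 4), so
grade is statistically identifiable from contrast and extent. Gaussian
noise (σ = 0.03) is added to both contrasts.

What the phantoms deliberately do **not** model: MRI physics (bias
fields, Rician noise, b-value synthesis), T2–ADC misregistration,
extraprostatic extension, and realistic lesion morphology. Passing the
learning tests therefore shows the pipeline is wired correctly and can
extract a graded contrast/size signal — it says nothing about clinical
performance, which in the source setting required hundreds of annotated
patients.

## Evaluation protocol

Dice is reported at image level (mean over lesion-bearing slices) and
patient level (3-D dice per stacked case volume, then mean; empty∧empty
defined as 1). Detection/classification counts are stratified by cutoff
(PI-RADS ≥ 3, ≥ 4, = 5 via the decoder's channel-selection scope; binary
low/high grade via the capsule branch). A prediction matches a
ground-truth lesion at IoU ≥ 0.1 ("same location" in the lenient
radiological sense; configurable). Patient-level decisions use the index
lesion, defined as the largest ground-truth lesion. Rates with zero
denominators are reported as missing, never as 0. Slices with several
lesions take the maximum class present.

Post-processing selects, over the whole case volume, the ordinal channel
with the most supra-threshold voxels as the final mask. On exactly
nested encodings all populated channels tie, so ties break toward the
higher channel, which recovers the encoded class; selection is per case
(not per slice) because PI-RADS is assigned per lesion. Components below
5 voxels are discarded as speckle. Lesion area is pixels × resolution²
(max over slices), volume adds slice thickness, and the equivalent
diameter is `2·√(area/π)`; "dimension" in the report lists all three
since clinical usage varies.

## Problem sizes and profiles

The default architecture profile realizes every published shape
(6×6×256 features, 32×8 primary capsules, two 16-D class capsules,
5×100×100 output) and is used by all shape-contract tests. A narrower
**desk profile** (widths 8/16/32/64, 8×4 capsules, 8-D class capsules)
keeps the identical topology and is used wherever a model is actually
trained — the package's CPU-scale configuration. Training experiments in
the test suite and the acceptance script use cohorts of a few dozen
phantom cases and ~30 epochs; these sizes are the package's desk-scale
defaults, chosen so a full run completes on one core while leaving the
paper-scale settings (300 epochs, five folds, batch 256) available in
`TrainConfig`.

## Known limitations

* The desk-profile capsule branch sees a weak grade signal early in
  training and can transiently favour the majority (high-grade) class;
  longer schedules separate the classes further.
* The channel-selection rule favours lower channels on real (non-nested)
  predictions, so the reported PI-RADS scope is conservative — a lower
  bound, as the term "scope" suggests.
* One optimizer step per case means the effective batch is small;
  gradient noise is higher than the paper-scale batch-256 setting.
* The engine is single-threaded NumPy; paper-scale training is out of
  reach by design, and no GPU path exists.
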