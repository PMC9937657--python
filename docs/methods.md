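# Methods

This note documents the models, estimators, defaults and design
decisions in `brainext`, and what the phantom-based tests do and do not
demonstrate about real MRI data.

## Segmentation backbone

The backbone is a slice-wise encoder/decoder. Each block is two 3×3
convolutions, each followed by batch normalization and an ELU; encoder
blocks are separated by 2×2 stride-2 max pooling, the first block
produces `base_channels` feature maps and each deeper block doubles
them. The default is five levels with 16 base channels and a 256×256
in-plane size; the test suite exercises a four-level, 8-channel, 64×64
instance of the same architecture. 2D kernels are used because rodent
and NHP acquisitions are strongly anisotropic through-plane, which makes
3D kernels a poor fit; per-slice masks are re-stacked into the original
3D grid afterwards.

The bottleneck carries an embedded-Gaussian nonlocal attention block:
queries/keys/values are 1×1 projections to C/2 channels, the affinity
between positions is a row-stochastic softmax over all spatial
positions, and the output projection is zero-initialized so the block
starts as an identity. The attention saliency exported for
visualization is the affinity mass each position receives, upsampled to
the slice size and min–max normalized.

The final head is a 3×3 convolution to one channel plus a sigmoid. (The
head kernel is switchable to 1×1: descriptions of this architecture are
ambiguous between a "1×1 convolution" and a "3×3 kernel", so both
variants are available for audit; the parameter-count difference is
8·`base_channels`.) The head bias is initialized to the foreground-prior
logit log(0.1/0.9) ≈ −2.2: brain occupies roughly 10 % of a head slice,
and starting near the class prior avoids the long false-positive
burn-in that the Dice loss produces from a p≈0.5 start.

Everything (forward, backward, Adam) is numpy; gradient correctness of
every layer and of the assembled network is verified against central
finite differences at 1e-5 tolerance in float64.

### Dropout placement and semantics

Spatial (channel-wise) dropout with rate 0.2 sits at the bottleneck and
the two deepest decoder levels. By default dropout is **inference-only**:
inactive during ordinary training, active in the Monte Carlo (`mc`)
forward mode. Rationale: batch-normalization running statistics must
describe the activation distribution the network sees at evaluation
time. If dropout is active while those statistics are accumulated, any
later clean re-estimation (including adaptation on the *source* domain
itself) shifts the calibration and measurably degrades Dice. With
inference-only dropout, re-adaptation on the source domain is a fixed
point, which is the property statistic-transfer relies on. Classic
train-time dropout can be switched back on via
`ModelConfig.dropout_in_training`.

### Statistics recalibration

Source training ends with one pooled-statistics pass over the
unaugmented training slices (the same estimator the AdaBN step uses,
pooling per-batch means/variances by the law of total variance). This
replaces the momentum-EMA statistics accumulated from augmented batches
during training. One estimator therefore owns calibration everywhere,
and adaptation deltas on the training domain reduce to sampling noise.

## Preprocessing

Intensities are normalized per volume as (V − p1)/(p99 − p1) with p1/p99
the 1st/99th percentiles over the whole volume, then clipped to [0, 1].
Percentiles are per-volume (not per-slice) so slices share one intensity
frame; clipping bounds the network input on the 2 % tails. Slices are
brought to the network size by bilinear resize (default) or center
crop/pad; crop/pad inverts exactly, resize inverts to within
interpolation (Dice ≥ 0.98 on smooth masks). 4D functional series use
the fifth time point (0-based index 4) for metric reporting.

Bias-field correction offers three modes. `off` is the default in the
prediction pipeline (the phantom generator's field is mild).
`homomorphic` is a built-in class-conditional log-residual estimator:
voxels are clustered into three intensity classes (1D k-means on log
intensity), the per-voxel log residual around its class mean isolates
the multiplicative field from genuine tissue contrast, and a heavy
Gaussian blur (σ = ¼ of each axis) keeps only its smooth component. A
naive log-domain lowpass cannot be used here: on a piecewise-constant
object it removes anatomy, not bias. `external_n4` delegates to
SimpleITK's N4 when that package is importable.

## Phantom generator

A phantom is a brain ellipsoid (optional low-order sinusoidal surface
wobble), a shell (dilated ellipsoid minus brain — skull/scalp
analogue), and background, with region means 1.0 / 0.55 / 0.10,
gamma-mapped, multiplied by a smooth product-of-cosines bias field and
corrupted by Gaussian noise (default SD 0.05). The default grid is
64×64×32 at 0.1×0.1×0.4 mm — rodent-like anisotropy. Ground truth is
the exact voxelized brain.

Geometry randomness (center jitter, wobble and bias phases) derives
from a hash of the spec itself; the `seed` argument drives only the
noise. Two phantoms from the same spec therefore share one mask with
independent noise — convenient for seed contracts — and `make_phantom`
is bit-reproducible under `(spec, seed)`.

Domain shifts move one axis each:

* **scanner** — noise SD +0.15·m, bias amplitude +0.35·m, gamma ×(1+0.8·m):
  field-strength/hardware changes;
* **modality** — contrast polarity inversion plus shell-mean remapping:
  sequence changes;
* **species** — shape change at a roughly preserved brain/FOV volume
  fraction (elongate a ×1.2, flatten b ×0.75 and c ×0.8, shell ×1.3).
  The volume fraction is preserved deliberately: in practice the field
  of view is chosen per species, so a species change shifts *shape*,
  not the foreground marginal. A pure foreground-fraction shift at
  matched intensities is a label-marginal shift that normalization
  -statistic transfer provably mis-corrects and that does not
  correspond to real acquisitions.

`degrade` blurs (σ up to 2 voxels) and re-noises (SD up to 0.25) at a
graded level with the mask untouched, manufacturing quality variation
for the uncertainty-vs-Dice experiments.

**What the phantoms do not emulate:** real tissue texture and internal
brain structure, partial-volume effects, k-space/sequence physics,
pathology, motion, and multi-subject anatomical variability. Passing
the phantom suite shows the machinery is correct and behaves as designed
under controlled shifts; it does not certify accuracy on any real
cohort.

## Training, baselines and transfer

Supervised training: Adam (0.9/0.999), Dice loss with smoothing
constant 1 over the whole batch, batch 16, 50 epochs by default,
learning rate 1e-4 for the source role and 1e-5 for targets.
Augmentation draws rotation ±10°, scale 90–110 % and translation ±10 px
per axis, applied identically to slice and mask (nearest-neighbour for
the mask). Slices without foreground are kept — the network must learn
to reject non-brain slices. Cross-validation splits are by volume.

The two baselines: *training from scratch* (random init on the target
labels) and *fine-tuning* (all weights continue at the target rate,
running statistics updating batch-by-batch — deliberately plain
semantics; its known small-sample fragility, BN statistic churn from
tiny cohorts, is part of what the transfer framework is measured
against).

`semisup_train` is the full transfer recipe: AdaBN once before epoch 0;
normalization statistics frozen thereafter (statistics are owned by the
adaptation step — re-estimating them from two-volume batches is strictly
noisier); per epoch, supervised hybrid loss (L1 + Dice) on the labels;
from epoch T_sl, Monte Carlo screening of the unlabeled volumes with
the previous-epoch snapshot, admission of the minimum-uncertainty
volume per screening minibatch (ties to the lowest volume id;
a lowest-q quantile rule is available), and a λ_sl-weighted Dice term
toward the frozen snapshot prediction. The pseudo-label is the
snapshot's deterministic prediction; the stochastic samples are used
only to rank volumes. Pseudo-labels are stored soft and binarized at
0.5 inside the Dice term. The ‖·‖ fidelity term is read as the per-pixel
L1 mean. "Iteration" is interpreted as epoch, so θ_{t−1} is the
end-of-previous-epoch snapshot.

## Uncertainty

T = 10 Monte Carlo samples by default (7 when matching a seven-rater
panel). Aleatoric and epistemic components are bounded by 1/4 for
binary probabilities; epistemic equals E[p²] − p̄² algebraically, which
the tests verify to 1e-10. The volume scalar is the mean total
uncertainty over the plausible-brain region (p̄ > 0.05, a choice — the
reduction is otherwise undefined), min–max normalized across the cohort
being screened.

## Evaluation

Dice is computed on whole 3D volumes; two empty masks score 1 with a
warning. HD95 extracts boundaries as foreground voxels with a
6-connected background neighbour (volume faces count as background),
measures directed nearest-boundary distances in mm, takes the
95th percentile with linear interpolation, and returns the larger
directed value; it is validated to 1e-9 against an all-pairs
brute-force oracle. Volumes are voxel count × voxel volume; agreement
reports the least-squares slope of predicted on annotated volume, the
mean difference, and bias ± 1.96·SD limits of agreement.

## Problem sizes used by the test suite and acceptance script

The package's own experiments run a four-level, 8-channel, 64×64
network: 30 source phantoms (8 training epochs) for source competence;
10 + 10 scanner/modality volumes for zero-label adaptation; the species
few-label comparison with 2 labels + 40 unlabeled volumes over three
seeds (T_epoch 4–6, T_sl 2, 3–5 MC samples — the T_sl/T_epoch ratio
follows the 20/50 default); 20 degraded phantoms for the
uncertainty-quality correlation; reproducibility checks re-run
shortened (2-epoch) instances twice and compare bit-for-bit. These
sizes were chosen as the smallest cohorts at which the measured effects
are stable.

## Known limitations

* The numpy backbone is single-device and CPU-bound; it is written for
  correctness and desk-scale experiments, not large-cohort training.
* AdaBN helps when the domain gap lives in intensity statistics
  (contrast, noise, bias). On pure geometry shifts it is approximately
  neutral, and on label-marginal shifts (foreground-fraction changes)
  it can mis-correct — an intrinsic property of the method, visible in
  the phantom experiments.
* The homomorphic bias corrector assumes a few roughly constant-intensity
  tissue classes; heavily textured anatomy violates that assumption.
* Uncertainty calibration is not addressed: scores rank volumes but are
  not probabilities.
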