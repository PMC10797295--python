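# Methods

## Scope and data model

`pkseg` analyzes paired, co-registered whole-body mouse CT and PET volumes
with integer organ label maps. Arrays are stored `(axial, coronal,
sagittal)` = (z, y, x); the axial axis is the coarse one (0.80 mm
canonical spacing vs 0.15 mm in-plane), so the network patch
`(64, 160, 160)` reads directly off array shape. NIfTI-1 with RAS+ world
coordinates is used throughout, the qform preferred over the sform.
Acquisition metadata (injected dose in MBq, isotope and its half-life,
body weight in grams, timepoint in hours post-injection, tumor status)
travels in a JSON sidecar per volume. Registration transforms are
*applied*, never estimated: `apply_affine_registration` composes
`moving_affine⁻¹ · T⁻¹ · reference_affine` and resamples with linear
(images) or nearest (labels) interpolation.

Cross-validation groups all of a subject's timepoints into one fold by
default (`split_by="subject"`), avoiding leakage of a subject's anatomy
between train and test; per-volume splitting is available behind the same
flag since either reading of "randomly split" is defensible.

## Preprocessing

The order is crop → normalize → resample; normalization statistics are
computed at native resolution.

* **Cropping.** The foreground box is the tightest box around the largest
  connected component above a threshold, defaulting to the 60th percentile
  of the in-volume CT histogram. A percentile (rather than an absolute
  Hounsfield value) is robust to scanners with uncalibrated intensity
  scales; the largest-component rule discards the animal bed and distal
  structures.
* **CT normalization** is global: pooled foreground voxels over all
  training cases are clipped at their 0.5/99.5 percentiles, and the
  pooled clipped mean/std define `(v − μ)/σ`. Clip percentiles and the
  crop percentile are config, not facts; the fingerprint is serialized as
  JSON and reused at inference.
* **PET normalization** is per volume (Z-score with the *population*
  standard deviation), because PET intensity scale depends on dose, decay
  and reconstruction, so no global statistic is transferable.
* **Resampling** targets (0.80, 0.15, 0.15) mm; output shape is
  `max(1, round(shape · spacing / target))`, linear for images and
  nearest for labels (cubic interpolation is avoided to prevent ringing
  on PET). Nearest interpolation guarantees no label values are invented.

## Network

Encoder–decoder with skip connections at equal resolution. Strides
entering successive levels are `(1,2,2), (1,2,2), (2,2,2), (2,2,2),
(2,2,2), (2,1,1)`: the first two act only on the fine in-plane axes and
the last only on the axial axis, giving the level shapes
`(64,160,160) → (64,80,80) → (64,40,40) → (32,20,20) → (16,10,10) →
(8,5,5) → (4,5,5)` with channels `32, 64, 128, 256, 320, 320, 320`
(doubling capped at 320). Each level has two blocks of convolution →
instance normalization → leaky ReLU (slope 0.01); downsampling is the
first convolution of each level with the entering stride; upsampling is a
transposed convolution with kernel = stride (pure interleaving, no
overlap); a 1×1×1 head maps to the class scores. Levels whose entering
stride is `(1,2,2)` use `(1,3,3)` kernels so the receptive field grows
roughly isotropically in millimetres; other levels use `3×3×3`.

The whole network, including backpropagation, is implemented on
NumPy/BLAS: convolutions are evaluated as one matrix product per kernel
offset ("shift-and-matmul"), which keeps peak memory near the activation
size and runs a full-patch forward pass in about a minute on one CPU
core. Gradients are verified against finite differences in the test
suite. `compute_shape_schedule` predicts every level's shape and channel
count, and a live forward pass records actual encoder shapes so the
architecture is auditable end to end.

## Training

Unstated-by-convention choices, all exposed in `TrainConfig`:

| parameter | default | rationale |
|---|---|---|
| loss | soft Dice + cross-entropy | standard for this family; Dice drives sparse organs, CE stabilizes early training |
| optimizer | SGD, Nesterov-style momentum 0.9 | small-batch 3D segmentation default |
| learning rate | 0.03, polynomial decay (power 0.9) | chosen from convergence experiments on single-volume phantom training at desk scale |
| patches / epoch | 10 | batch size is 1 (CPU); an epoch is a sampling unit, not a data pass |
| foreground oversampling | 0.5 | half of patches are centered on a random voxel of a *random present organ* (class-balanced), so the spleen is sampled as often as the liver |
| augmentation | axis flips; optional intensity jitter | light, geometry-preserving |
| seed | one master seed | fans out to init, sampling and augmentation; recorded in the log |

Subset models restrict training data by modality (single-channel input),
timepoint, or tumor status, or subtract one organ from the targets: the
organ is relabelled to background and removed from the model's class
list, so such a model structurally cannot emit it. Predictions map class
channels back to the original organ label ids.

## Inference

Sliding windows with 50% overlap; overlapping score maps are blended with
a Gaussian window (σ = patch/8) centered on each patch; per-voxel argmax
with ties resolved to the lowest class index. Inputs smaller than the
patch are symmetrically zero-padded and the output cropped back.

## Pharmacokinetics

Units are centralized: concentrations kBq/cc, doses MBq externally / kBq
internally, weights g, times h. PET voxel values are assumed to be
decay-corrected-to-scan-time activity concentration (the scanner
convention); the *injected dose* is decay-corrected to the timepoint,
`D(t) = D₀·2^(−t/T½)`, with isotope half-lives in a named table (Cu-64:
12.701 h — a physical constant of the package, with F-18, Ga-68 and Zr-89
also provided). Then

* `%ID = 100 · Σ c_i · v_voxel / D(t)`,
* `%ID/cc = %ID / V_organ` — the organ-mean definition; a per-voxel
  `%ID/cc` map is available but not the default,
* `SUV_x = c_x / (D(t)/weight)` for x ∈ {mean, max, min}, using body
  weight (not lean mass),
* AUC exposure is the trapezoidal integral of `%ID/cc` over the observed
  timepoints only — no extrapolation to t = 0 or beyond the last scan.

`fit_monoexponential_half_life` recovers a clearance half-life by
log₂-linear regression; applied to late timepoints (6–48 h) it estimates
the slow phase once the fast phase (sub-hour half-life) has decayed away.

## Evaluation statistics

DSC and VD are computed by exact voxel counting. Decisions on points the
definitions leave open:

* **Both masks empty → DSC 1** (perfect agreement on absence); pinned by
  a test.
* **VD is asymmetric**: the reference volume is the denominator and must
  be nonempty.
* **U95** is implemented as `1.96·√(sd(e)² + RMSE²)` with `e = y − x`, a
  standard published form of the 95% uncertainty; the exact variant in
  circulation differs between fields, so this is a documented choice.
* **Relative errors** (MARE, RMSRE) skip entries with reference value 0
  and report the skipped count rather than failing the series.
* **Model comparisons** use one-sided Welch (unequal-variance) t-tests of
  parent > subset by default — per-organ DSC variances differ markedly
  between organs — with a paired and a pooled variant behind flags;
  Bonferroni adjustment divides α = 0.05 by the number of comparisons.

## Saliency

Grad-CAM for dense prediction: the class score is the *sum* of the target
class's pre-argmax score map over the patch; channel weights are spatial
means of the gradients at a chosen convolution (default: the last decoder
convolution before the head); the heatmap is the rectified weighted sum,
upsampled to the patch grid and max-normalized. Summation over space is
the documented aggregation choice; any spatial weighting could be
substituted by masking the score gradient.

## Phantom generator

The generator emulates the statistical structure of a longitudinal
microbubble/nanoparticle study: default cohorts of 71 subjects × 5
timepoints (1, 3.5, 6, 24, 48 h), ~35% healthy / ~65% tumor-bearing, with
per-subject randomized geometry (±8% radii), kinetics (±20% amplitudes),
dose (±10%) and body weight (~N(22 g, 2 g)).

* **Geometry**: pairwise-disjoint ellipsoids (heart, two lung lobes,
  liver, spleen, two kidneys, optional tumor abutting the body wall)
  inside a rounded-cylinder trunk, over an animal-bed slab. Positions and
  radii are fractions of the field of view, so phantoms render at any
  grid size; organ volumes at the default 64×96×96 grid (0.8×0.3×0.3 mm)
  are realistic for a ~22 g mouse (heart 0.18 cc, lungs 0.28 cc, liver
  1.2 cc, spleen 0.09 cc, kidneys 2×0.12 cc). Disjointness is checked at
  rasterization in continuous space, so it holds at every resolution.
* **Kinetics in %ID/cc**: blood-pool organs (heart, lungs, kidneys, and a
  faint whole-body background) follow two-phase clearance
  `A_f·2^(−t/T_f) + A_s·2^(−t/T_s)` with T_f ≈ 0.4–0.5 h and T_s drawn
  per subject from 5–11 h and *shared* across blood-pool organs (one
  systemic clearance); accumulation organs (liver, spleen, tumor) follow
  `P·(1−2^(−t/T_up))·2^(−t/T_wash)`. Defaults give heart ≈ 8 %ID/cc at
  1 h vs liver ≈ 2, reversing by 24–48 h. Tumor-bearing subjects get a
  15% higher splenic peak (a documented off-target shift); healthy
  renders otherwise differ only by tumor absence, which is test-pinned.
* **PET image**: `c = %ID/cc / 100 · D(t)` in kBq/cc, spatially uniform
  within each organ plus additive Gaussian noise (σ = 3 kBq/cc default).
  Noise is *not* clipped at zero: clipping would bias organ means upward
  at the low signal levels of late timepoints and corrupt half-life
  recovery. Uniformity keeps every PK readout closed-form
  (`analytic_truth`), which is what makes the phantom an oracle.
* **CT image**: per-tissue constants (air −1000, body 40, lungs −700,
  liver 80, bed −300, …) plus Gaussian noise (σ = 15).

What the phantom does *not* emulate: anatomically realistic shapes,
intra-organ heterogeneity (available as a texture flag, excluded from
oracle tests), Poisson counting statistics, scanner physics (attenuation,
scatter, partial-volume blur), respiratory motion, or registration error.
Tests passing on phantoms therefore demonstrate the *pipeline's*
correctness — geometry, units, statistics, learnability — not clinical
segmentation accuracy on real animals, which requires real training data
at scale.

## Problem sizes used in the test suite

Training-dependent tests run at desk scale as the package's own choice of
test conditions: a reduced network (patch 32³, 3 resolutions, 16 base
kernels) trained for 50 epochs × 8 patches on one phantom volume prepared
at (0.8, 0.6, 0.6) mm — coarser in-plane than the canonical geometry so a
32³ patch spans organ-scale context. This configuration reaches mean
foreground DSC ≈ 0.92 on its training volume. The end-to-end CLI smoke
test uses a 6-subject, 2-timepoint cohort on a 48×64×64 grid with a
3-epoch training run. The full-size architecture audit runs one forward
pass at (64, 160, 160) with random weights.

## Known limitations

* Batch size is fixed at 1 (instance normalization makes this the normal
  regime for 3D segmentation, but there is no gradient accumulation).
* The transposed convolution uses kernel = stride; overlapping
  transposed kernels are not implemented.
* No multi-GPU or multi-process training; CPU threads follow BLAS.
* Registration transforms must be supplied; estimation is out of scope.
* Radiation dosimetry beyond %ID-based exposure (equivalent dose, organ
  residence time) is not computed.
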