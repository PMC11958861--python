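# Methods

## Problem and model

The package learns a mapping from a brain-masked T1-weighted MR volume to
the corresponding [¹¹C]UCB-J DVR volume — a unitless parametric map of
synaptic (SV2A) density normalized to a cerebellar reference region,
DVR = (BP_ND + 1)/(BP_ND[Cb] + 1), where BP_ND[Cb] is the arithmetic mean of
BP_ND over the reference voxels (the reduction is a package choice; the
quantity itself only fixes "the reference value").

The regressor is a symmetric 3D convolutional encoder-decoder:

* encoder — four 3×3×3 convolutions with stride 2 and filter counts
  32/64/128/256 (configurable ladder), ReLU after each;
* decoder — four 3×3×3 transposed convolutions with stride 2 and the
  mirrored filter ladder, ReLU after each;
* output — one stride-1, single-channel 3×3×3 convolution, rectified by
  default because DVR is physically non-negative (`final_relu=False`
  disables this).

There are no skip connections and no pooling; downsampling is by
convolution stride.  Every layer uses valid padding, so an input of extent
n maps to ⌊(n−3)/2⌋+1 per encoder layer, (n−1)·2+3 per decoder layer, and
n−2 at the output: 64³ patches produce 61³ outputs and the 240×240×160
whole-brain inference window produces 237×237×157.  Training targets are
center-cropped to the output shape.  `output_shape` exposes the exact
per-layer trace and rejects inadmissible inputs naming the failing layer.

Important structural consequence: with no skip pathways all spatial detail
flows through the 16×-downsampled bottleneck, so predictions are smooth
reconstructions — the well-known blur of L2-trained convolutional
translators.  This matters for the desk-scale configuration below.

The convolution engine is written in numpy (im2col unfolding plus one BLAS
matrix product per layer and the mirror-image column scatter for gradients
and transposed convolutions), with Adam and the staircase learning-rate
schedule lr(step) = lr₀ · γ^⌊step/100⌋.  Everything is float32 and fully
deterministic for a fixed seed on CPU.

## Synthetic cohorts

Real paired MRI/PET data are clinical and not redistributable; the phantom
module generates cohorts that preserve the features the analysis depends
on, and nothing more:

* Geometry — nested soft ellipsoids: head, cerebrum with a cortical GM
  ribbon around a WM core, ventricular CSF, and a separate cerebellum
  blob.  Soft boundaries (logistic transition ≈ 1–2 voxels) stand in for
  partial-volume mixing.  Default grid 64³ at 2 mm (48³ used in the
  scaled-down experiments); the full acquisition grid 256×256×207 at
  1.219×1.219×1.231 mm is available by configuration.
* Atlas — the cerebrum is partitioned into named angular wedges covering
  the ROI set of the clinical analysis (frontal, insula, hippocampus,
  amygdala, occipital, parietal, precuneus, putamen, pallidum, temporal,
  anterior cingulate) plus the cerebellum label used as DVR reference.
  Wedges are anatomy-free stand-ins: they exist so that the per-ROI
  reporting, the regional disease effects, and the group t-tests are
  exercisable end to end.
* T1 — per-tissue intensity mixture (GM 0.45, WM 0.80, CSF 0.08, arbitrary
  units) modulated by a smooth multiplicative bias field (±5%) plus
  Gaussian noise (SD 0.01), zero outside the head.
* Synaptic density — BP_ND = base + gain · GM-density · m(ROI), with
  base 0.3, gain 2.5 and per-ROI multipliers (cerebellum 0.2, giving the
  reference-region contrast that makes DVR informative).  The linear
  GM→SV2A link is the generative premise that makes ground truth known and
  parameter recovery testable.
* Scanner resolution — the clean BP_ND map is smoothed with a Gaussian PSF
  of 6 mm FWHM before noise; parametric PET is intrinsically
  resolution-limited, and omitting this step would make the translation
  target sharper than any real DVR map.
* Disease effects — an atrophy factor shrinks GM probability (displaced
  volume becomes CSF) *before* both the T1 and the BP_ND are synthesized,
  so structural and functional changes co-vary; regional SV2A multipliers
  depress binding (AD: hippocampus 0.70, temporal 0.80, amygdala 0.85,
  frontal/parietal 0.90, atrophy 0.88; SZ and CUD: milder frontal /
  temporal / hippocampal reductions).  The AD pattern follows the reported
  direction of SV2A loss; SZ/CUD magnitudes are configurable modeling
  choices, not quantitative claims.
* Dose noise — voxelwise Gaussian with SD = noise_scale/√dose (count-
  statistics analogy), clipped at zero; noise_scale 0.5 so a 15.7 mCi
  (cohort-mean) scan has DVR-scale noise SD ≈ 0.08 while sub-5 mCi scans
  are visibly noisier.  With this calibration the measured-vs-noiseless
  DVR MSE of a normal-dose phantom is ≈ 0.005, the same order as the
  clinical translation errors the analysis reports.
* Manifest — diagnosis counts drawn exactly from a requested ratio (the
  clinical composition HC:SZ:AD:CUD = 83:24:34:19 at n=160), normal doses
  from N(15.71, 4.32²) truncated above the low-dose threshold, low doses
  uniform in (2.2, 4.8); the low-dose flag is dose < 5 mCi.

What the phantoms do **not** model: MR sequence physics, PET sinograms and
reconstruction artifacts, kinetic time-activity curves, motion, scanner
harmonization, real cortical folding, and real inter-subject anatomical
variability (only a mild global GM scale jitter, 4% SD).  Passing the
desk-scale tests therefore shows that the pipeline recovers a known
GM→SV2A mapping under controlled conditions — not that the architecture
reaches clinical accuracy on real data.

## Preprocessing

Brain mask = (GM+WM+CSF probability > 0.5); the threshold is conventional.
The mask is applied to the T1 and both DVR maps; each T1 is divided by its
within-mask 99th-percentile intensity before patching so network inputs are
bounded near [0, 1].  Resampling (trilinear for intensities, nearest for
labels) places voxel centers at world = (index + ½)·voxel_size with a
shared corner origin; co-registration itself is out of scope (phantoms are
generated aligned, external data must arrive aligned).

## Training and inference

Patches are cropped jointly from the T1/DVR pair with corners uniform over
all valid positions (an optional minimum-brain-fraction filter exists,
default off); each optimization step draws its batch's participants
uniformly with replacement, so an epoch consumes batch × steps patches
(400 at the full-scale defaults).  Validation loss is monitored on a fixed
set of patches drawn once; no early stopping and no validation-based model
selection — final-epoch weights are returned by default, with an optional
selection-free tail average of the last K epochs' weights
(`tail_average_epochs`).  Adam moments are the conventional (0.9, 0.999).

Whole-volume prediction tiles the volume with input windows whose output
windows are pairwise disjoint and exactly cover the grid; only the small
valid-padding margin is mirror-padded and edge windows shift inward over
real content rather than into padding.  Because the network is trained on
windows whose content distribution matters (there is no full translation
equivariance through the strided bottleneck), windows are spread evenly and
each voxel is produced by the window whose content is most central for it:
the most volume-centered window claims its full output range and windows
toward the edges claim only the remainder on their side.  A context-crop
option (`output_crop`, default a quarter of the tile output per side in the
pipeline) controls the window spacing.  Single-window prediction is
bit-identical to a direct forward pass.

## Evaluation

The four image-quality measures are computed inside an explicit evaluation
mask (the brain mask by default):

* MSE — mean squared voxel difference;
* SSIM — the *global-moment* form (one set of masked means, variances and
  covariance, constants c₁=(0.01·L)², c₂=(0.03·L)² with L the masked
  dynamic range of the ground truth).  This is deliberately the single-
  window statistic, not the sliding-window SSIM; a Gaussian-window variant
  (`ssim_windowed`) is provided for comparison only.  Global SSIM is a
  lenient moment-matching index and its values are not comparable to
  windowed SSIM values;
* percentage bias — 100·(μ_truth − μ_pred)/μ_truth over a region, signed
  (negative = overshoot), reported per whole image and per atlas ROI;
* Pearson ρ — voxelwise correlation, plus a joint 2D histogram with the
  least-squares line of predicted on true values.

Group comparisons use Welch's two-sample t-test (two-sided) on per-
participant ROI means; the equal-variance variant is switchable.  Empty
ROIs yield flagged rows rather than disappearing.  Aggregate tables
(mean ± SD by diagnosis, low-dose rows separated) recompute exactly from
the per-participant rows.

## Cross-validation design

Folds are built from the manifest: low-dose participants are placed in
every fold's test set and never in train/validation.  Eligible ids are
dealt per diagnosis round-robin into k base test groups (every participant
tested at least once); training sets are drawn so each diagnosis count is
within one participant of the cohort proportion.  The published sizes
(130/7/23 from 160 with 5 fixed test ids) cannot form a disjoint
exact-coverage partition over 10 folds, so `strict_sizes` (default) tops
test sets up by resampling eligible ids — a participant may then be tested
in more than one fold — while `strict_sizes=False` keeps a pure rotation
with near-equal test sizes.  Leave-one-disease-out holds out one diagnosis
entirely (low-dose ids of the remaining diagnoses are excluded from
training and validation).

## Desk-scale configuration

The self-contained experiment used by the acceptance script trains on a
24-phantom cohort (48³ voxels, HC:SZ:AD:CUD = 12:4:4:4, 3 low-dose) with
the reduced ladder 8/16/32/64, 32³ patches, batch 2, 30 epochs × 50 steps.
Four optimization settings are adapted to this 10×-smaller problem: the
initial learning rate is 5·10⁻³ with staircase decay 0.93 per 100 steps
(1,500 steps is too few for the full-scale schedule to converge, and a
decayed endpoint stabilizes the global amplitude of the prediction); the L2
loss is restricted to brain voxels (with whole-patch loss, the blurry
reconstruction's spill across the mask boundary leaves a systematic
whole-image bias of +7–12% at this scale); patches are resampled until at
least half their voxels are brain (more supervision per step); and the
returned weights are the average of the final 12 epochs, a selection-free
tail average that damps end-of-training amplitude wander.  Inference tiles
with 32³ windows (the training patch size).  Held-out reconstruction error
sits near the low-dose noise floor, so the low-dose denoising margin is
the tightest of the desk-scale checks and varies with the cohort
realization.
Problem sizes throughout the test-suite and acceptance script are chosen so
the whole run completes in minutes on a single CPU core.

## Numerical and degenerate-case conventions

Shape mismatches always raise — metrics never broadcast.  Constant inputs:
SSIM of two identical constants is 1 (the regularization constants resolve
the 0/0, with L falling back to 1 when the masked range is zero); Pearson
and the least-squares fit reject constant inputs; percentage bias rejects a
zero reference mean; DVR rejects an empty reference region — each with a
distinct error type.  The t-test returns (0, 1) for two identical
degenerate groups.  Weight initialization is He fan-in scaling with a
recorded seed; training aborts with a diagnostic on a non-finite loss.

## Known limitations

* The phantom geometry is ellipsoidal and the atlas is a wedge partition;
  ROI-level numbers exercise the reporting machinery but have no
  anatomical meaning.
* The no-skip valid-padding architecture bounds achievable sharpness; at
  desk scale predictions are visibly smoother than the ground truth, and
  percentage bias is the most sensitive of the four metrics to this blur.
* Global SSIM values are systematically higher than windowed SSIM values
  and should not be compared across conventions.
* The numpy engine is single-threaded CPU code; it is sized for the
  desk-scale experiments, not for 150-epoch full-resolution training.
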