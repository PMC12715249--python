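# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where the published protocol left
the design open.

## The problem setting

The analysis classifies structural T1-weighted brain MRI into three
diagnostic stages — cognitively normal (CN), mild cognitive impairment
(MCI), and Alzheimer's disease (AD) — from a compact 2D representation:
ten coronal slices around the anterior commissure tiled into one
512×512 image. Coronal planes cut the hippocampal formation
perpendicularly, which is where early neurodegeneration shows; the
2D-grid trick lets standard 2D classifiers consume near-3D anatomical
context at a fraction of 3D-CNN cost. The class mix follows clinical
prevalence (≈43% AD, 34% MCI, 23% CN, a 1.92:1 max/min imbalance), which
is mild enough to look harmless and severe enough to collapse
high-capacity models onto the majority class — hence the emphasis on
imbalance mitigation and imbalance-aware evaluation.

## Phantom cohorts

Real data for this problem are access-controlled, so the generator
renders geometric head phantoms that carry exactly the structure the
downstream stages consume:

- an ellipsoidal head (scalp tier) containing a brain with a cortical
  GM shell and WM core; intensities default to CSF 30 / GM 80 / WM 120
  (arbitrary units) with the T1 ordering WM > GM > CSF enforced;
- two ventricular cavities (CSF) and two hippocampal blobs (GM
  intensity, embedded in the WM core so they are visible by contrast).
  Deep-structure *positions* sit at fixed fractions of the WM core so
  phantoms remain valid at any supported volume size; their *sizes* are
  absolute millimetres scaled by the atrophy parameters, so labelled
  voxel counts scale as the cube of the scale factor (tested at ±10%);
- diagnosis grades the anatomy: hippocampus scale 1.0/0.85/0.70 and
  ventricle scale 1.0/1.15/1.30 for CN/MCI/AD. The direction follows
  dementia pathophysiology (hippocampal atrophy, compensatory
  ventricular enlargement); the magnitudes are package defaults chosen
  large enough that a tiny classifier can learn them, and are exposed in
  `CohortSpec.class_effect_table`;
- per-patient anatomical jitter (multiplicative, sd 0.02 on both scales)
  so that within-class variation exists without overwhelming the class
  effect; additive Gaussian noise (sd 3) gives a clean-scan SNR near 30;
- demographics: age from class-conditional normals (CN 72±6, MCI 74±6,
  AD 77±6, clipped to 55–95), sex Bernoulli(1/2), three scanner ids.
  These exist so stratification has non-degenerate strata;
- artifacts for QC testing: a motion ghost (half-FOV-shifted replica
  along the posterior–anterior axis, amplitude 0.5·severity of the
  source), a smooth low-order polynomial bias field (±50%·severity
  within the head), and a noise burst.

Default volume: 96×112×96 voxels at 2 mm isotropic; 1 mm is supported
through `PhantomParams`. Tests and the analysis scripts use 64×72×64 at
2 mm, which keeps every structure comfortably inside the volume while a
full cohort preprocesses in minutes on one CPU.

What the phantoms deliberately do **not** emulate: real cortical
geometry, partial-volume effects, site/scanner intensity differences,
DICOM semantics, or longitudinal change. Passing tests therefore show
that the *pipeline machinery* is correct and that class-graded atrophy
of this magnitude is recoverable; they say nothing about classifier
accuracy on clinical data.

## Preprocessing

**Quality control.** SNR = mean(head) / sd(background), with the head
taken as the largest connected component above the Otsu threshold.
Rejection iff SNR < 20 or motion score > 0.3; otherwise
`q = 0.4·snr_norm + 0.3·(1−motion) + 0.3·uniformity`. A raw SNR cannot
enter a [0,1]-weighted score, so `snr_norm = min(SNR, 40)/40`, which
maps the rejection threshold 20 to 0.5. The motion score is the
regression amplitude of the half-FOV-shifted volume within background
voxels where the shifted head is bright, scaled so a half-intensity
replica scores 1.0 — on injected ghosts the score tracks severity
almost exactly. Uniformity is 1 − IQR/median of the low-pass-filtered
bright-tissue band; the band is selected on a flat-fielded image (the
flat-field scale tracks the head radius) so that a bias field cannot
steer the selection it is supposed to be caught by.

**Brain extraction.** Threshold at robust_min + 0.3·(robust_max −
robust_min) using 2nd/98th percentiles (the fractional-intensity
behaviour of standard brain-extraction tools), largest connected
component, 3×3×3 closing, hole filling, and a Gaussian-softened mask
edge; far background is exactly zero.

**Spatial normalization.** 12-parameter affine (3 translations mm, 3
Euler rotations, 3 log-scales, 3 shears) mapping template physical
coordinates to moving coordinates about the volume centers. Similarity
is the correlation ratio (32 template-intensity bins, η² of moving
intensity explained by binned template intensity). Initialization from
center of mass and per-axis second moments; optimization by Powell in
two stages (rigid, then full affine) on a 2× coarsened pair; the final
resample is trilinear on the template lattice. If the optimizer ends
worse than the initialization, the initialization is returned (the cost
never exceeds its starting value) and a warning is logged. Recovery on
known transforms is well inside 0.5 voxel / 2% scale. Nonlinear warping
is deliberately out of scope; registration is affine-only. Because all
phantoms are rendered on a shared lattice, the pipeline exposes
`register=False` (the default for the analysis drivers) — registration
is validated by its own transform-recovery tests rather than re-run on
every scan.

**Intensity normalization.** Three-class k-means on masked intensities
(highest-mean class = WM; fewer than 100 WM voxels is an error),
z-scoring by WM mean/sd, optional quantile matching to a reference
histogram, clipping at the 99.5th percentile, linear rescale to
[0, 255]. A population reference histogram is not distributable, so the
default reference is accumulated from the training split of the current
run (never from validation/test).

**Grid construction.** Slice index = origin_y + round(offset /
spacing_y) for offsets (−8…+10 mm); each coronal plane is bicubic-resized
to width 102 × height 256; slices 1–5 (posterior) tile the top row and
6–10 the bottom (5·102 = 510 wide, 2·256 = 512 high); a final bicubic
resize bridges 510→512 and the result is quantized to 8 bits. The
102×256 reading is the only one whose tiling composes to ~512².
Left-right orientation is never flipped. Offsets are interpreted
relative to the anterior-commissure analogue.

## Splitting

Patients — never scans — are assigned 70/20/10 by largest remainder
within strata of (diagnosis, age group <70/70–80/>80, sex), after a
seeded shuffle of patients sorted by id (input-order invariance).
Strata with fewer than 3 patients are pooled within diagnosis before
apportionment. Scans always follow their patient, which also settles
longitudinal leakage. `verify_no_leakage` checks patient-set
disjointness first and then, optionally against a scan-level manifest,
that every scan sits in its patient's split. The default seed is 42
throughout.

## Imbalance mitigation

Plans are pure arithmetic (weights = max/count; SMOTE synthesis up to
the majority; undersampling down to the minority) and reproduce the
study-scale numbers exactly from the printed training counts.
Borderline-SMOTE-1: a minority point is DANGER if among its m = 10
nearest neighbors (any class) the other-class count is in [m/2, m);
synthesis interpolates a DANGER seed toward one of its k = 5 nearest
same-class neighbors with u ~ U(0,1); if no DANGER points exist, the
whole minority class seeds. The feature space is configurable and
defaults to flattened downsampled grids (64×64, d = 4096), since the
protocol never states a SMOTE feature space for images. Resampling only
ever touches the training split. The combined strategy is SMOTE
resampling followed by focal-loss training; cost-sensitive weights and
the focal α vector are kept separate (α = (0.45, 0.34, 0.22) ordered
CN/MCI/AD so the rarest class gets the largest α).

Losses clip probabilities at 1e−7. Focal loss with γ = 0 and α = 1
reduces exactly to cross-entropy (tested); all losses are nonnegative
and zero only at their optimum.

## Models

`squash(s) = (‖s‖²/(1+‖s‖²))·s/‖s‖` with squash(0) = 0. Dynamic routing
initializes logits at zero (uniform couplings; literal zero *couplings*
would not be normalizable), then for r = 3 iterations: softmax over
output capsules, coupled sum, squash, logit update by û·v. The public
primitive implements exactly this. Inside the CapsNet the coupled sum is
divided by the total coupling mass per output capsule (a weighted mean):
with tens of thousands of primary capsules the plain sum drives squash
deep into saturation where gradients vanish, and the normalized form is
invariant to the primary-capsule count. Desk-scale training adapts the
channel-shared routing transform over a frozen seeded random
convolutional stem, treating couplings as constants in the gradient —
the usual approximation to backpropagating through routing. The
end-to-end classification properties are carried by the baseline CNN
(one conv layer, one hidden dense layer, softmax), which trains fully by
backprop.

Architecture at the 512-input scale: 256 9×9 stride-1 filters, 32
channels of 8-D primary capsules from 6×6 stride-2 kernels, three 16-D
class capsules. Routing weights are shared across spatial positions
within each primary channel, and the reconstruction decoder
(48→512→1024→64², weight 0.0005) targets a 64×64 downsampled image;
with per-position routing weights at this geometry the transform alone
would need ~7.7·10⁸ parameters, which no stated total is consistent
with. The analytic parameter count is ≈7.14 M.

Training: Adam (lr 0.001), decay ×0.9 every 100 epochs, global-norm
gradient clipping at 0.5, batch 16 for capsules / 8 for the CNN, early
stopping on validation loss with patience 50 (defaults; tests use
smaller budgets), best parameters restored. Training refuses to start
if the leakage check has not passed. Runs are bit-deterministic for a
fixed config.

## Evaluation

Label coding is ordinal — CN = 0, MCI = 1, AD = 2 — so the "MSE" metric
(mean squared coded difference × 100) penalizes CN↔AD confusions 4×
adjacent-stage ones; this is the only coding consistent with the
degenerate-predictor values (all-AD → 124%, all-MCI → 66%). Balanced
accuracy is (macro sensitivity + macro specificity)/2 — the only
definition under which every single-class predictor scores exactly 50%,
matching the degenerate rows. Precision/F1 use 0/0 → 0. Micro ROC AUC
flattens one-vs-rest label/score pairs (ties count 1/2; all-AD one-hot
scores give 57%); macro averages per-class AUCs, with single-class truth
reported as 0.5 by convention. MCC uses the generalized multiclass
covariance formula. Table-style percentages round half away from zero.

The bias index has no canonical formula; the default is total-variation
distance between predicted and true class distributions, normalized by
the distance of a point mass on the predictor's modal class, so any
single-class collapse scores exactly 1.00 and a distribution-matched
predictor 0. The formula is a configurable callable, and only the
forced 1.00 collapse case is treated as exact. An "imbalance index" is
not implemented: no defining formula is available.

Model ranking min-max normalizes each criterion to [0,1] (constant
columns → 0), sorts by performance score descending, and breaks ties by
top-5 accuracy descending then parameter count ascending.

## Problem sizes and verification

The test suite runs everything at desk scale on one CPU: phantoms at
64×72×64 ×2 mm, cohorts of 12–300 patients, models at 32–64-pixel input.
Every metric is checked against an independent brute-force
implementation on 1000 random confusion matrices and against
scikit-learn where an equivalent exists; SMOTE synthesis is verified to
interpolate strictly between real minority rows; registration is
verified on known synthetic transforms; the full pipeline smoke-runs in
well under a minute and is manifest-hash reproducible. Directional
properties mirror the study's qualitative findings: a trained classifier
beats the 33.3% three-class chance level by ≥15 balanced-accuracy points
on a 300-patient cohort, and the combined mitigation strategy does not
reduce minority-class (CN) sensitivity across three cohort seeds.

## Known limitations

- Phantom realism is intentionally minimal (see above); effect sizes are
  larger than clinical ones so that desk-scale models can recover them.
- The capsule network trains only its routing head at desk scale; no
  claim is made about full CapsNet training dynamics.
- Affine-only registration; no nonlinear warping, no multi-site
  harmonization.
- The bias index and the SMOTE feature space are package conventions
  where the protocol is silent; both are configurable.
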