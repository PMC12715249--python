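# coronal-caps

A desk-scale, fully tested re-implementation of a three-class dementia
classification analysis from structural MRI: **CN** (cognitively normal),
**MCI** (mild cognitive impairment), **AD** (Alzheimer's disease /
dementia). Real cohorts for this problem live in access-controlled
archives, so the package ships a seeded phantom-brain generator with the
statistical structure the analysis assumes, and every downstream stage —
preprocessing, splitting, imbalance mitigation, modelling, evaluation —
runs end to end on synthetic data with deterministic results.

It is written for researchers who want to study the *methodology* of
this kind of pipeline — slice-grid construction, leakage-free splitting,
class-imbalance handling, capsule routing, imbalance-aware metrics —
without access to the original imaging data or GPU-scale training.

## What is implemented

**Phantom cohorts** (`coronal_caps.cohort`). Ellipsoidal head phantoms
with T1-like tissue contrast (WM > GM > CSF), two hippocampi and two
ventricles whose sizes are graded by diagnosis (hippocampus scale
1.0 / 0.85 / 0.70 and ventricle scale 1.0 / 1.15 / 1.30 for
CN / MCI / AD), Gaussian noise, and injectable motion-ghost, bias-field
and noise-burst artifacts. Class mix defaults to the clinical prevalence
pattern 22.5% CN / 34.2% MCI / 43.3% AD.

**Five-stage preprocessing** (`coronal_caps.preprocess`):

1. *Quality control* — SNR, motion and uniformity estimates; reject iff
   SNR < 20 or motion score > 0.3, else
   `q = 0.4·min(SNR,40)/40 + 0.3·(1−motion) + 0.3·uniformity`.
2. *Brain extraction* — fractional-intensity threshold (0.3), largest
   connected component, 3×3×3 morphological closing, hole filling, soft
   (gradient-weighted) edge.
3. *Affine spatial normalization* — 12-DOF registration (translation,
   rotation, scale, shear) by correlation-ratio optimization with
   center-of-mass / second-moment initialization.
4. *Intensity normalization* — WM z-scoring from a 3-class intensity
   segmentation, optional histogram matching to a training-split
   reference, 99.5th-percentile clipping, rescale to [0, 255].
5. *Grid construction* — ten coronal slices at −8…+10 mm (2 mm apart,
   18 mm anterior–posterior span around the anterior-commissure
   analogue), each resized to 102×256, tiled 5×2 (posterior row on
   top), final bicubic resize to exactly **512×512, 8-bit** — the
   classifier input unit.

**Patient-level splitting** (`coronal_caps.split`) — stratified by
(diagnosis, age group <70 / 70–80 / >80, sex), seeded, 70/20/10 by
largest remainder on patient counts; all scans follow their patient, and
`verify_no_leakage` machine-checks that no patient straddles splits.

**Imbalance mitigation** (`coronal_caps.mitigation`) — inverse-frequency
class weights `w_c = max_count / count_c`, Borderline-SMOTE-1
oversampling plans and synthesis, random undersampling, and the losses:

- weighted cross-entropy `mean(−w_y log p_y)`,
- focal loss `mean(−α_y (1−p_y)^γ log p_y)` with γ = 2,
  α = (0.45, 0.34, 0.22) for (CN, MCI, AD),
- capsule margin loss
  `Σ_k T_k max(0, m⁺−‖v_k‖)² + λ(1−T_k) max(0, ‖v_k‖−m⁻)²`
  with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5.

**Models** (`coronal_caps.models`) — the squash nonlinearity, dynamic
routing-by-agreement (r = 3 iterations, logits updated by `û·v`), a
capsule network head (256-filter 9×9 stem; 32×8-D primary capsules with
6×6 stride-2 kernels; three 16-D class capsules; ~7.1 M parameters at
the 512-input scale), a small CNN baseline, and a deterministic Adam
trainer with gradient clipping (0.5), learning-rate decay (×0.9 / 100
epochs) and early stopping. Everything is plain numpy with hand-written
gradients.

**Evaluation** (`coronal_caps.metrics`) — confusion matrices, per-class
precision/sensitivity/specificity/F1 (0/0 → 0), macro and weighted
averages, balanced accuracy defined as *(macro sensitivity + macro
specificity)/2*, ordinal MSE with the coding CN=0 / MCI=1 / AD=2, ROC
AUC (micro and macro), macro AUC-PR, multiclass MCC, a bias index that
scores 1.0 for any single-class collapse, degenerate-predictor fixtures,
and a criterion-normalized model-ranking procedure.

## Worked example

Reproducing the imbalance arithmetic from the study's training-set
composition (2203 CN / 3325 MCI / 4222 AD images):

```bash
$ python analysis/04_imbalance_plans.py
training counts:        {'CN': 2203, 'MCI': 3325, 'AD': 4222}
inverse-freq weights:   {'CN': 1.92, 'MCI': 1.27, 'AD': 1.0}
SMOTE synthesis counts: {'CN': 2019, 'MCI': 897, 'AD': 0}
undersample removals:   {'CN': 0, 'MCI': 1122, 'AD': 2019}
```

The weights are the majority count divided by each class count (the AD
class is the reference at 1.0); SMOTE synthesizes every class up to the
majority count; undersampling removes down to the minority count.

Evaluating a degenerate all-AD predictor on the study's test
composition (447/677/859) exposes class collapse that plain accuracy
hides:

```bash
$ python analysis/05_degenerate_metrics.py
 predictor  accuracy ...  balanced_accuracy  mse_percent  roc_auc_micro  bias_index
    all-AD        43 ...                 50          124             57        1.00
```

43% accuracy but exactly 50% balanced accuracy (no discrimination), an
ordinal MSE of 124% (CN→AD confusions cost 4×), and a bias index of
1.00 (total collapse onto one class).

The numbered scripts under `analysis/` run the full sequence: cohort
generation, preprocessing with QC, splitting with leakage verification,
the mitigation plans, degenerate-metric fixtures, an end-to-end training
run, and the mitigation-strategy comparison. Each writes its tables
under `results/`.

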