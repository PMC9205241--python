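# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `sonomtl`. Every empirical number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## Tasks and loss

Each image carries a malignancy label `bm ∈ {0,1}`, a nodal-metastasis
label `alnm ∈ {0,1}` and a metastatic node count. The labels obey the
clinical hierarchy `alnm = 1 ⇒ bm = 1`; node count ≥ 1 exactly when
`alnm = 1`. Benign images are flagged `alnm_defined = false`: nodal status
is not a meaningful supervision target for a benign mass, so by default
their ALNM cross-entropy is masked out (`alnm_bce_mask_policy =
"malignant_only"`). Nodal-burden variants label a malignant image positive
when the patient's node count is at least n (n = 2, 3, 4) and are trained
as separate single-head runs.

The training loss is `L_all = λ·L_HL + L_BCE` with

* `L_BCE` — the equal-weight average of the malignancy head's mean binary
  cross-entropy (all samples) and the nodal head's mean BCE (unmasked
  samples). Probabilities are clamped to `[1e-7, 1 − 1e-7]` before logs.
  If a batch contains no unmasked sample the nodal term is dropped with a
  warning rather than averaged as a zero.
* `L_HL = (1/N) Σ max(0, ŷ₂ − ŷ₁ − m)` — the hierarchical hinge with
  margin `m = 0.1`. Its sub-gradient at the kink is defined as inactive
  (standard hinge convention, measure-zero set). By default the hinge is
  applied to *all* batch samples (`hl_scope = "all_samples"`): for benign
  images the hinge is the only force acting on the nodal score, which is
  precisely the consistency pressure the loss exists to provide. Both the
  masking policy and the hinge scope are switchable for ablation.

**Hinge weight.** λ = 0.05 is the reference full-scale setting, selected
on a validation cohort under a 200-epoch schedule (~25k optimizer steps).
The desk-scale default is **λ = 1.0**: a constraint's cumulative influence
is proportional to the number of optimizer steps it acts over, so
compressing the schedule ~20× (to ~1.3k steps) rescales λ by the same
factor that the learning rate is rescaled (see below). At desk scale with
λ = 0.05 the hinge's effect on test-time inconsistency is below seed
noise; at λ = 1.0 it is the clear effect reported in the README, with
per-task AUCs unchanged within 0.006.

## Model

`small_resnet` is a four-stage residual CNN built directly on numpy:
a 3×3 stem convolution, then three down-sampling residual blocks
(3×3 stride-2 conv → BN → ReLU → 3×3 conv → BN, plus a 1×1 stride-2
projection skip), global average pooling, and one fully connected sigmoid
head per task (default widths 8/16/32/64, input 48×48, ≈75k parameters).
Batch normalization uses batch statistics in training and running
statistics in evaluation, making eval-mode outputs deterministic and
batch-size independent (asserted in tests). Heads are independent given
the shared features: zeroing one head cannot change another's outputs.

All layers implement explicit forward/backward passes; the backward pass
is verified against float64 central finite differences to ~1e-9 at layer
and whole-model level, in both BN modes. No deep-learning framework is
involved, which is also why no pretrained large backbone is offered: the
consistency mechanism under study is backbone-agnostic, and the desk-scale
backbone trains on one CPU in seconds per epoch.

Checkpoints are versioned containers: an `.npz` of all weights and BN
running statistics plus a JSON sidecar with the architecture, task list
and seed.

## Training

Adam (β = 0.9/0.999), step schedule `lr = lr0 · 0.1^⌊epoch/step⌋`.
The reference full-scale recipe is lr0 = 1e-4, 200 epochs, step 50; the
desk defaults compress the schedule at the same 4:1 epochs-to-decay ratio
to **15 epochs, step 5**, and raise lr0 to **2e-3** — a backbone trained
from scratch in ~200–800 steps needs proportionally larger steps (at
lr0 = 1e-4 the desk model stays at the class prior, AUC ≈ 0.5). Batch
size (unreported in the reference study) defaults to 8: the smaller,
noisier batches spread the sigmoid outputs beyond the class priors within
the short schedule, which matters because the inconsistency metrics are
threshold-based. No early stopping; the final-epoch checkpoint is
evaluated. No class re-weighting.

Four arms cover the ablation design: `single_bm`, `single_alnm` (each one
head; the nodal arm trains on ALNM-defined records only), `multitask`
(both heads, λ forced to 0) and `multitask_hl`. Repeat r re-seeds
initialization, shuffling and augmentation with `base_seed + r`; the
patient split is fixed once for all repeats. The margin grid search
(`train.margin_grid_search`) trains one hinge arm per candidate and picks
the margin maximizing the mean of the two validation AUCs, ties toward the
smaller margin; the default grid contains the reference margin 0.1.

## Data pipeline

Training inputs are box-level RoI crops expanded by a 20% context margin
per side, augmented (train mode only) by random area-fraction scale-crop
(0.8–1.0), horizontal flip (p = 0.5), brightness/contrast jitter (±20%,
the grayscale analogue of color distortion), then bilinear resize to the
model input. Evaluation and radiomics use resize only — augmentation is
structurally bypassed outside train mode. Output intensities stay in
[0, 255]; magnitudes are declared defaults, not inferred values.

The patient-level split assigns `ceil(n·0.3)` patients to test (ties
toward test — this rounding, not `round`, reproduces the 640/1491 split
of a 2131-patient cohort) and 20% of the remainder to validation; it is a
pure function of the sorted patient IDs and the seed, and no patient ever
straddles splits (asserted on every split).

## Synthetic cohort generator

Each patient gets one lesion (an orientation-jittered spiculated ellipse)
and 1–4 views of it; views share morphology up to small pose jitter, with
independent speckle. Labels: `bm ~ Bernoulli(0.85)`,
`alnm | bm=1 ~ Bernoulli(0.27)`, node count from
{1: .31, 2: .18, 3: .15, 4: .16, 5+: .20} — the class ratios of the
emulated ~2131-patient cohort. Benign patients draw more views per patient
(mean ≈ 3.3 vs ≈ 2.0) because in the emulated cohort benign lesions carry
about three times as many images each; image-level prevalence is therefore
milder (~77% malignant) than patient-level (85%).

Morphology carries the signal; every class shift is `effect_size` times
that parameter's own SD, so `effect_size = 0` renders all classes
identically distributed (KS-tested) and `effect_size = 2` makes a
threshold on spiculation alone separate malignancy with AUC ≈ 0.92:

* malignancy: higher boundary spiculation, blurrier margins, darker
  (hypoechoic) core;
* nodal positivity (within malignant): brighter peritumoral halo and
  mildly larger size; node count nudges size further;
* 25% of benign lesions draw a "reactive" bright halo from the
  node-positive distribution (adenopathy-like mimics). This overlap is
  what makes hierarchy violations *possible*: a nodal head that never
  sees benign supervision scores these mimics high while the malignancy
  head correctly scores them low. Without it no arm ever produced an
  inconsistent prediction and the hinge had nothing to do.

Speckle is multiplicative Rayleigh-amplitude noise on a smoothed Gaussian
random field (first-order fully-developed-speckle approximation);
`speckle_scale = 0` switches noise and background texture off exactly,
leaving analytically checkable binary ellipses. The bounding box is the
tight axis-aligned box of the pre-blur lesion mask, 0-based half-open.
Datasets round-trip exactly through PNG + VOC XML + CSV manifest.

What the generator does **not** model: point-spread-function convolution,
attenuation/time-gain compensation, acoustic shadowing, multi-vendor
appearance differences, DICOM metadata, and any pixel-level ground-truth
mask. Passing tests on this cohort demonstrate the mechanics and the
direction of the consistency effect, not clinical performance.

## Evaluation

Thresholded metrics count a prediction positive iff score > τ (τ = 0.5;
a score exactly at τ is negative). Undefined ratios (empty class) are NaN,
never exceptions; `acc = (se·P + sp·N)/(P+N)` is asserted on every
evaluation. AUC is trapezoidal over all thresholds and equals exhaustive
Mann–Whitney pair counting with ties at half (tested exactly to n = 200).
ALNM and burden metrics are computed over ALNM-defined (malignant) test
images, the population on which those labels exist; inconsistency rates
are computed over *all* test images, where the benign contradictions live.
Metrics are per image by default; per-patient score pooling is available
behind a flag.

Across-repeat summaries report mean, sample SD, and a 95% band
`mean ± t₀.₉₇₅,ₙ₋₁·sd` — the descriptive band that matches the
"mean ± sd (lo, hi)" reporting style it mirrors (for mean 0.782,
sd 0.01, n = 5 it gives ±0.028, reproducing the printed interval widths);
`ci_mode="sem"` selects the conventional standard-error interval
(simulated coverage ≈ 0.95 vs ≈ 0.997 for the sd band). Model
comparisons use a one-sample two-sided t-test against a scalar baseline
and Welch's t-test between repeat vectors; zero variance with zero
difference reports p = 1 by convention.

The two inconsistency definitions (thresholded contradiction; continuous
margin violation) are both reported because the reference study names two
error types without defining them; ours are the two natural readings and
both are configurable.

## Grad-CAM

Channel weights are the global-average-pooled gradients of the head's
pre-sigmoid output with respect to a chosen stage's activation maps
(default: the last stage before pooling); the map is the rectified
weighted sum, bilinearly upsampled and max-normalized (an all-zero map
stays zero). Because each head is GAP + linear, the last-stage gradients
are available in closed form (head weight / map area), which the tests
exploit as an independent oracle.

Radial profiles average the heatmap in equal-width annuli around the
image center out to half the diagonal. On wide-context crops the nodal
head's response concentrates on the central lesion/halo zone (inner-half
mean ≈ 0.28 vs outer ≈ 0.11 across the five hinge-trained repeats) —
consistent with the peritumoral localization the task's cue implies.
**Limitation:** the malignancy head's CAM on this small zero-padded
backbone shows a border bias (response rising toward the crop edge at the
6×6 CAM resolution), so a center-dominance claim is not supported for
that head at desk scale; a deeper backbone with larger CAM resolution
would be needed to study it.

## Radiomics baseline

Per-RoI features (no augmentation): 17 first-order histogram statistics;
GLCM contrast/dissimilarity/homogeneity/energy/correlation/ASM plus
entropy at distances 1–3 averaged over the four standard 2-D angles
(scikit-image co-occurrence matrices, 32 gray levels); and 11 GLRLM
statistics averaged over four directions (~52 features by default — the
inventory is a configurable setting, not a fixed count, since the
selection step makes it non-critical and no shape features are computed
without masks). Constant-image degeneracies (undefined correlation) are
imputed to 0 with a warning.

Feature selection is Boruta: per-iteration permuted shadow copies, a
random-forest importance comparison against the best shadow, and
accumulating two-sided binomial hit tests at α with Bonferroni correction
over the feature inventory; undecided features at the iteration budget are
returned as *tentative*, never confirmed. Constant columns are rejected
up front. The selection forest (100 trees, depth 7) is deliberately
decoupled from the final classifier — a random forest with 300 trees and
a depth cap of 300 (the reference study's stated depth; effectively
unbounded at RoI scale, and exposed alongside the tree count since the
figure may well describe the ensemble size). If selection confirms
nothing, the classifier falls back to all features with a warning.

## Determinism and problem sizes

Every stochastic step (generation, splitting, initialization, shuffling,
augmentation, shadow permutations, forests) derives from explicit seeds;
two runs of the same config produce byte-identical summary JSON (asserted
on a smoke config). BLAS threading is pinned to one thread in the test
harness so trajectories are reproducible.

Default problem sizes are chosen for a single CPU: 300 patients
(~680 images) at 128×128, model input 48×48, 15 epochs, 5 repeats —
the two-arm consistency experiment runs in ~4 minutes, the full test
suite in ~10, and the acceptance script in ~5. The full-scale recipe
(200 epochs, lr0 1e-4, λ 0.05, larger inputs/widths) remains expressible
through the same configs.
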