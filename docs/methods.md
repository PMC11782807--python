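# Methods

## Problem and model

`cinefuse` estimates scalar pulmonary hemodynamic parameters — mean
pulmonary artery pressure (mPAP, mmHg), pulmonary artery wedge pressure
(PAWP, mmHg), and pulmonary vascular resistance (PVR, Wood units) — from
four cardiac MR cine views: two-chamber (2CH), four-chamber (4CH),
right-ventricular long-axis (RVLA), and a representative short-axis (SAX)
mid-slice. Each view is a 20-phase cine loop, so one examination is 80
2-D frames. The reference standard for these parameters is right heart
catheterization (RHC), an invasive procedure; the model is a non-invasive
surrogate regressor.

The architecture is built from three shared components:

1. **Frame encoder** `E: R^{256x256} -> R^D`. One parameter set encodes
   all 80 frames of an exam.
2. **Attention Feature Fusion Block (AFFB)**. Given component features
   `f_1..f_N` (any `N`), a shared affine scorer produces raw attention
   scores `a_i = w^T f_i + b`; a softmax yields normalised weights
   `alpha = softmax(a)`; the fused feature is the convex combination
   `sum_i alpha_i f_i`. Fusion is therefore dimension-preserving,
   permutation-equivariant in its weights, and a fixed point on identical
   inputs.
3. **Regression layer** `R: R^D -> R`, a single affine map. Because
   fusion preserves the feature dimension, `R` can score *any* feature —
   raw frame, intermediate summary, or final.

Fusion proceeds in two stages. Stage 1 applies the AFFB view-wise (the 4
views of each phase -> 20 *spatial summaries*) and phase-wise (the 20
phases of each view -> 4 *temporal summaries*). Stage 2 fuses those 24
summaries into the final feature, whose regression output is the model's
prediction. One exam therefore yields 80 frame features, 24 summaries,
1 final feature, and 105 per-feature predictions. A single AFFB instance
is shared across all 25 fusion calls (a per-stage variant is available via
`ModelConfig.shared_affb=False` for ablation). The parameter count is
independent of the number of views and phases.

The training objective is the mean squared error between predicted and
RHC-measured values. Each hemodynamic target gets its own independently
trained model; the three predictions together drive the precapillary-PH
rule (below).

## Encoder profiles

The package implements the network, its optimiser (Adam), and
reverse-mode differentiation directly on NumPy arrays (`cinefuse._autodiff`,
`cinefuse.nn`). The default encoder is a lightweight strided convolutional
network: average-pool to 64 px, a 4x4/stride-4 patch convolution (8
channels), a 2x2/stride-2 patch convolution (16 channels) — both with
leaky-ReLU activations — global average pooling, a linear projection to
`D = 64`, and a LayerNorm on the feature vector. Non-overlapping
patch convolutions were chosen so the backward pass is a pure reshape
(no scatter-accumulate), which is what makes CPU training of the full
80-frames-per-exam pipeline practical. The leaky ReLUs and the output
LayerNorm address two failure modes observed in a narrow encoder trained
from scratch: irreversible unit death, and global-average-pooled features
whose variance is orders of magnitude below the unit-variance target
scale, which strands the affine head in a long rescaling transient. Deeper backbones can be added
through the `ModelConfig.encoder` registry; the architecture contracts
(shared encoder/AFFB/head, feature counts, attention algebra) do not
depend on encoder depth.

Grayscale frames enter the encoder as a single channel. The attention
scorer and the regression layer both include bias terms. Weights are
He-initialised from the run seed; no pretraining is used.

## Preprocessing

Raw cine series are standardised in three steps, in this order:

1. **Intensity**: clip at the 3rd/97th percentile of *all pixels of the
   series* (linear-interpolation percentiles), then map affinely to
   [0, 1]. Series-wide rather than per-frame percentiles preserve
   inter-frame intensity relations. A degenerate series (p3 == p97)
   maps to zeros with a warning rather than erroring, so blank phantoms
   survive the pipeline.
2. **Geometry**: bilinear resampling to 0.94 mm/pixel (output size
   `round(dim * spacing / 0.94)`), then a centred crop or symmetric
   zero-pad to 256 x 256, i.e. a 240 x 240 mm field of view. Pad value 0
   matches the black-canvas convention of the perturbation analysis.
   Crop centering uses the geometric image centre; an offset parameter
   exists for heart-centred cropping.
3. **Augmentation** (training only): per cine series, one random
   horizontal flip (p = 0.5), shift (±16 px), scale (0.9–1.1), and
   rotation (±15°), composed into a single affine transform applied
   identically to all 20 frames, preserving temporal coherence. The four
   views of one exam draw independent transforms by default
   (`shared_across_views` inverts this). Magnitudes are deliberately
   mild to keep anatomy plausible, and all are configurable.

## Training

Adam with learning rate 1e-4, weight decay 1e-8 (L2 folded into the
gradient), batch size 10, up to 1000 epochs with early stopping —
patience 50 epochs on validation MSE, restoring the best-validation
checkpoint. Splits are disjoint at the exam/patient identifier level
(65/15/20 convention). One seed drives weight initialisation, shuffling,
and augmentation; identical seeds reproduce histories and weights
bit-for-bit.

Three optional occlusion-robustness mechanisms can be enabled for
training (all off by default, all training-only): *view dropout*
replaces a whole cine series with a black series with some probability —
the fusion design explicitly tolerates missing views, and dropout makes
that tolerance real rather than nominal; *keep-one-view* blacks out all
but one random view of an exam, the extreme missing-view case; and
*region erasing* blanks, per occluded exam and independently per view,
either a random ellipse (semi-axes between a tenth and a third of the
frame) or one of the exam's own Gaussian-dilated chamber regions, shared
across the 20 phases of a series. Chamber-shaped erasure is applied
symmetrically over all chambers, so it prefers none of them. Per-view
erasure inside an occluded exam is probabilistic (p = 0.6), so the
training distribution contains both the "one view occluded, rest intact"
condition that the chamber-importance analysis actually applies and
multi-view occlusions, which block the shortcut of simply discarding any
occluded series.

The purpose of all three is to put the blacked-out inputs used by the
chamber mask/paste analysis inside the training distribution: a shallow
encoder trained only on intact images otherwise treats any occluded exam
as out-of-distribution and its perturbed predictions measure
distribution shift, not information content. Deep clinical-scale
backbones acquire this robustness implicitly; a desk-scale encoder needs
it induced.

Numerical choice: targets are z-scored on the training split during
optimisation, and the scaling is folded back into the affine regression
head after the best checkpoint is restored (`w <- w*sd`, `b <- b*sd + mu`).
Predictions — including per-feature predictions — are therefore always in
target units, while the optimiser sees unit-variance targets, which
shortens the transient where the head climbs from its near-zero
initialisation. Desk-scale experiments in this package use a learning
rate of 3e-3 and ≤60 epochs; with unit-variance targets this reaches the
same plateau as the long-schedule default in a few minutes of CPU time.

## Evaluation

MAE, Pearson correlation (PCC), and `R^2 = 1 - SS_res/SS_tot` with
`SS_tot` about the ground-truth mean — so `R^2` can be negative for a
predictor worse than the mean, and is rejected outright for constant
ground truth. Bland–Altman agreement reports the mean difference
(pred − truth) and `bias ± 1.96 * SD` limits with the sample (n−1) SD
estimator, the conventional choice for limits of agreement.

Precapillary pulmonary hypertension in the absence of left-heart disease
is flagged when **mPAP > 20 mmHg and PVR > 2 WU and PAWP ≤ 15 mmHg**,
with the strict/inclusive boundaries exactly as written. Applying the
rule to predicted and true triples gives the confusion matrix, accuracy,
sensitivity, and specificity.

## Explainability

*Per-feature performance.* All 105 features of each exam pass through the
shared regression layer; each feature's predictions are scored over the
dataset. Degenerate (constant) prediction sets report NaN PCC with a
warning rather than a fabricated 0.

*Attention weights.* Normalised weights are averaged over exams per
fusion group — view-wise (rows of 4), phase-wise (rows of 20), stage 2
(24) — and never renormalised across groups. Averaging normalised
weights keeps each group summing to 1. The per-view mean of the
view-wise rows ranks view preference.

*Chamber perturbation.* Binary chamber masks (LV/LA in 2CH; all four in
4CH; RV/RA in RVLA; LV/RV in SAX) are dilated by Gaussian filtering
(sigma 4 px, kernel truncated at radius 16 px) and thresholding strictly
above zero — "strictly" so an empty mask stays empty and dilation is
monotone; a single pixel dilates to a 33 x 33 square. Dilation hides
exact area and boundary-shape information. Two complementary
perturbations are applied to the preprocessed input at test time, against
a frozen model: **masking** zeroes the dilated region in the selected
view(s), leaving everything else intact; **pasting** keeps only the
dilated region of the selected view(s) on an otherwise black input. For
any mask, the two perturbed exams sum back to the original pixel-exactly.
Test-set PCC is recomputed per mode x (view | all views) x chamber; cells
exist only for the 10 valid view/chamber pairs plus 4 "all views" cells.
Masks default to one per frame (phantom masks are per-phase since
chambers contract); a single per-series mask is accepted and broadcast.

## Synthetic phantoms

The generator emulates the *structure* of a clinical cohort, not its
appearance: four views x 20 phases x 256 x 256 at 0.94 mm/px, elliptical
chambers with distinct blood-pool intensities, a myocardial ring around
ventricles, Gaussian-blurred edges (sigma 1 px), background noise, and
per-exam pose jitter (shift ±6 px, rotation ±8°, size ±5%, random
intensity gain). Ventricular semi-axes shrink by up to 20% along a
piecewise-sin² cyclic profile whose extremum sits at phase 9
(end-systole); atria expand in anti-phase at half amplitude.

Labels: mPAP ~ truncated normal 39.7 ± 14.5 mmHg (> 0); PVR = 0.25·mPAP −
3 + N(0,1), floored at 0.1 WU; PAWP ~ N(12.9, 5.4) clipped to [2, 35] —
parameter values chosen to emulate a PH referral cohort, with the
PVR link strong enough that both diagnostic classes occur in a default
draw. These links are generator conventions, not clinical claims.

The *signal map* assigns each (view, chamber) a coefficient linking the
z-scored target to the chamber's linear size; the default plants signal
only in (SAX, RV) at 0.20 per SD (z clipped to [−2.5, 2.8] so geometry
stays inside the frame). Chambers with zero coefficient are rendered
independently of the target, so information placement is known exactly.
Pre-dilation masks equal the rendered chamber pixels exactly (chambers
are painted from their analytic interiors; a later-painted chamber claims
contested pixels, and signal-carrying chambers paint last).

What phantoms do **not** emulate: tissue texture and MR contrast
mechanics, flow and breathing artifacts, valve planes, trabeculation,
inter-patient anatomical variability beyond pose/size jitter, or any
physiological coupling between chamber geometry and PAWP. Passing the
signal-recovery experiment shows the pipeline *can* find and attribute a
planted morphological signal; it does not certify clinical performance.

## Signal-recovery experiment

`cinefuse.experiments.run_signal_recovery` is the integration benchmark:
a 260/60/80 cohort (the 65/15/20 convention at 400 exams) with inputs
block-averaged to 64 px — sizes chosen so the full run (generation,
training, and all three analyses) completes in minutes on one CPU core.

Training is a two-phase curriculum. Phase 1 (60 epochs, learning rate
1e-3) fits the regression with the area-preserving per-series
augmentations — flip, shift (scaled to the pooled grid), rotation — but
not scale jitter: chamber *size* is the phantom's only information
channel, so 0.9–1.1 scaling multiplies the apparent signal by 0.81–1.21
and acts as label noise at this problem size (with clinically rich,
multi-feature inputs this objection disappears, which is why the
package-wide default keeps scale augmentation). Phase 2 (100 epochs,
learning rate 5e-4) fine-tunes with the occlusion menu — view dropout
p = 0.05, per-exam region erasing p = 0.35, keep-one-view p = 0.10 — and
selects its checkpoint on a *robust validation set*: each validation
exam in three conditions (intact, single view visible, one chamber
masked), so the returned model is accurate under occlusion by
construction rather than by checkpoint luck. Ordering the phases
matters: a model that cannot yet solve the task responds to heavy
occlusion by hedging toward the mean, whereas a converged model only has
to make its attention scorer tolerant of missing structures.

The experiment checks that the trained model recovers the target (test
PCC and R²), that SAX ranks first both by temporal-summary PCC and mean
view attention, that masking (SAX, RV) causes the largest single-view
PCC drop, and that pasting (SAX, RV) best preserves PCC — the three
analyses agreeing on the planted location. An OLS regression on the true
end-systolic SAX RV area provides the clean upper bound for comparison.
One caveat inherent to mask perturbation on these phantoms: the dilated
mask hides shape and exact area, but the size of the blacked-out hole
itself still correlates with chamber size, so the masked (SAX, RV) cell
retains some residual correlation rather than dropping to zero — the
analysis ordering, not the absolute drop, is the meaningful readout.

## Known limitations

- The default encoder is far shallower than clinical-scale backbones;
  with realistic image complexity it would underfit. The design isolates
  the fusion architecture, which is the object of interest here.
- Tolerant (variable view/phase) fusion is supported by the AFFB by
  construction but strict 4 x 20 input checking is the default.
- Training supervises only the final-feature prediction; per-feature
  performance of intermediate features is emergent, not supervised.
- Non-isotropic pixel spacing, SAX stack handling (beyond a designated
  mid-slice), and bias-field correction are out of scope.
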