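# cinefuse

Non-invasive estimation of pulmonary hemodynamics from multi-view cardiac
MR cine series, with built-in model explainability.

Right heart catheterization (RHC) is the reference standard for measuring
mean pulmonary artery pressure (mPAP), pulmonary artery wedge pressure
(PAWP), and pulmonary vascular resistance (PVR) — the quantities that
define pulmonary hypertension and its precapillary form — but it is
invasive. `cinefuse` implements a regression model that predicts these
scalars directly from four standard cine CMR planes (2CH, 4CH, RVLA, and a
SAX mid-slice; 20 phases each), plus the analyses needed to understand
*what* the model uses: per-feature predictive performance, attention-weight
inspection, and chamber-level mask/paste occlusion. A synthetic cardiac
phantom generator with a plantable, ground-truth-known signal makes the
entire pipeline runnable and testable without clinical data.

Audience: researchers in cardiac image analysis who want a transparent,
dependency-light reference implementation of attention-based multi-view
cine fusion and its occlusion explainability.

## The model

Each of the 80 frames of an exam is encoded by one shared encoder
`E: R^{256x256} -> R^D`. The Attention Feature Fusion Block (AFFB) fuses
any set of component features `f_1..f_N`:

    a_i   = w^T f_i + b          (shared affine scorer)
    alpha = softmax(a)           (nonnegative, sums to 1)
    fused = sum_i alpha_i f_i    (dimension-preserving)

Stage 1 fuses the 4 views of each phase (20 *spatial summaries*) and the
20 phases of each view (4 *temporal summaries*); stage 2 fuses those 24
summaries into the final feature, which a shared affine regression layer
`R: R^D -> R` maps to the prediction. Training minimises the MSE against
RHC labels (Adam, lr 1e-4, weight decay 1e-8, batch 10, early stopping).
Because fusion preserves dimension, `R` can score *every* one of the
80 + 24 + 1 features — that is the per-feature explainability — and each
fusion exposes its attention weights. Chamber importance is measured by
masking (zeroing a Gaussian-dilated chamber region) or pasting (keeping
only that region on a black canvas) and re-measuring test-set PCC.

The network, its optimiser, and reverse-mode autodiff are implemented on
NumPy inside the package; see `docs/methods.md` for the encoder profile,
numerical choices, and what the phantoms do and do not emulate.

## Worked example

```python
import numpy as np
from cinefuse import (CineFusionModel, PhantomConfig, TrainConfig,
                      generate_cohort)

# a small phantom cohort whose mPAP signal lives only in the SAX RV
cohort = generate_cohort(PhantomConfig(), n_train=40, n_val=10, n_test=10, seed=7)
model = CineFusionModel.from_cohort(cohort, target="mPAP", pool=4)
results = model.fit(TrainConfig(learning_rate=1e-3, max_epochs=40,
                                early_stop_patience=40, seed=7))
print(results.summary())

x_test, y_test = cohort.load_arrays("test", pool=4)
print(results.evaluate(x_test, y_test))

weights = results.attention_weights(x_test)
for view, w in zip(("2CH", "4CH", "RVLA", "SAX"), weights["view_mean"]):
    print(f"mean view-wise attention {view}: {w:.3f}")
```

Output:

```
Multi-view cine attention-fusion regression
===================================================
Target:            mPAP
Views x phases:    4 x 20  (80 frame features, 24 summaries)
Feature dim (D):   64
Trainable params:  2010
Epochs run:        40 (best at epoch 39)
Val MSE (z):       0.3253
Val MAE:           7.769
Val PCC:           0.821
Val R2:            0.294
===================================================
n=10  MAE=7.817  PCC=0.816  R2=0.498
mean view-wise attention 2CH: 0.245
mean view-wise attention 4CH: 0.162
mean view-wise attention RVLA: 0.201
mean view-wise attention SAX: 0.393
```

The test-set report reads: on 10 held-out phantom exams the model predicts
mPAP with a mean absolute error of 7.8 mmHg, Pearson correlation 0.82, and
R² 0.50 against the generator's ground truth. The view-wise attention
means show the model has learned to build its fused features preferentially
from the SAX view — which is exactly where the generator planted the
signal; the larger, longer-trained benchmark in
`cinefuse.experiments.run_signal_recovery` sharpens all of these numbers.
`results.per_feature_performance(...)` and `results.chamber_importance(...)`
provide the other two analyses (a 105-row feature table and the mask/paste
PCC grid); `cinefuse synth / train / predict / evaluate / explain` expose
the same pipeline on exam directories from the shell.

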