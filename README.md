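# restransnet

A hybrid residual-CNN / transformer classifier for predicting PD-1
(programmed cell death protein 1) expression status from tumour-centred CT
lesion patches, with the full clinical evaluation pipeline around it.

PD-1 status in hepatocellular carcinoma guides checkpoint-blockade
immunotherapy, but the reference assay — immunohistochemistry on resected or
biopsied tissue — is invasive, slow, and subject to sampling bias.  This
package implements a non-invasive image-based alternative end to end, for
researchers who want to train, evaluate, and interrogate such a model on
their own annotated CT patches (or on the built-in synthetic cohorts):

* **Preprocessing** — tumour-centred ROI cropping to 128×128 with
  boundary-preserving downscaling, [0, 1] normalisation, configurable
  augmentation, and patient-level 8:2 hold-out splitting.
* **Model** — a residual convolutional backbone (channels 16→32→64)
  feeding a 12-block pre-norm transformer over a 4×4 patch grid with a
  learned class token; the classifier reads only the final class-token
  state:  `Z = MSA(LN(X)) + X`, `Y = MLP(LN(Z)) + Z`, attention
  `softmax(QKᵀ/√d_k)V`, loss `L = −Σ(y log ŷ + (1−y) log(1−ŷ))`.
* **Class imbalance** — minority oversampling, class-distribution-reverse
  loss re-weighting, and a gradient penalty that shrinks (by λ, default 0.5)
  every per-sample gradient g_i involved in a pair with cosine similarity
  `g_i·g_j/(‖g_i‖‖g_j‖) > ε` (default 0.9) — countering the overfitting
  caused by oversampled duplicates.
* **Training** — SGD (lr 0.01, momentum 0.9, weight decay 5e-4, batch 128),
  lr ÷10 at epochs 50/100/150 with a 1e-5 floor, seeded and deterministic,
  best-test-AUC checkpointing.
* **Evaluation** — ACC/SEN/SPEC, ROC/AUC, decision-curve analysis net
  benefit, Mann–Whitney U, Kaplan–Meier curves with median 95% CIs, and the
  log-rank test between predicted PD-1 groups.
* **Interpretability** — feature maps from named layers and a class-token
  attention heatmap over the input.
* **Synthetic cohorts** — a seeded generator of 128×128 lesion patches whose
  texture differs by class, with per-patient geometry and class-linked
  survival times, so every stage is testable without clinical data.

The network trains on a compact NumPy reverse-mode autodiff engine included
in the package; no GPU framework is required.

## Worked example

Train the reduced architecture (2 transformer blocks, d=32) on a seeded
synthetic cohort with a strong class texture (effect size 3), then evaluate
on the held-out patients — a few minutes on one CPU:

```python
from restransnet.experiments import run_synthetic_benchmark

res = run_synthetic_benchmark(seed=0)   # 200 patients, 20 epochs, batch 32
print(res["test_acc"], res["test_auc"])
```

Output of this exact run:

```
cohort: 247 train / 57 test images
train_acc: 1.0
train_auc: 1.0
test_acc: 1.0
test_auc: 1.0
 epoch  train_loss  train_acc  test_acc  test_auc
     0    0.693382        0.5  0.245614  0.297342
     9    0.689431        0.5  0.754386  1.000000
    19    0.001482        1.0  1.000000  1.000000
```

The planted oriented texture is linearly detectable at effect size 3, so the
network separates the classes completely: test AUC reaches 1.0 by epoch 9
and the decision threshold calibrates by epoch 19.  On real CT data none of
these numbers transfer — see `docs/methods.md` for what the generator does
and does not emulate.

The same workflow is scriptable from the shell:

```bash
restransnet simulate --out cohort/ --n-patients 93 --prevalence 0.213 --seed 1
restransnet train    --data cohort/manifest.csv --out run/ --reduced --epochs 20
restransnet evaluate --checkpoint run/checkpoint.npz --data cohort/manifest.csv --out eval/
restransnet explain  --checkpoint run/checkpoint.npz --image cohort/images/P0000_000.png --out maps/
```

`evaluate` writes `metrics.json` (ACC/SEN/SPEC/AUC, and KM medians with the
log-rank p when the manifest carries survival columns) plus ROC and
decision-curve points as CSV; `explain` writes feature-map grids and the
class-activation overlay as PNG.

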