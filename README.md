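# fundus-laterality

Self-adaptive CNN training for **eye-laterality detection** from color fundus
photographs: which eye — left or right — does a retinal photograph show?
Laterality is a basic piece of clinical metadata that is often missing or
wrong in large fundus-image collections; the dominant visual cue is the optic
disc, which sits nasally (mirror-opposite sides in the two eyes) relative to
the central macula.

The package is aimed at researchers in automated retinal image analysis. It
provides the full pipeline — image normalization, four enhancement methods, a
GAP-headed CNN classifier, a monitor-driven *self-adaptive* training strategy,
class-activation-map (CAM) visualization, and binary-classifier evaluation —
exercised end-to-end on **synthetic fundus images**, so no clinical data or
GPU is required. The neural network (convolutions, batch normalization,
pooling, SGD with momentum, backpropagation) is implemented directly in numpy.

## The self-adaptive strategy

Training is monitored by a single scalar per epoch,

```
M = (1 − Accuracy) · Loss
```

computed on the validation set (smaller is better). Two mechanisms react to it:

* **Adaptive learning rate.** The rate starts at l₀ = 0.1. When Mₙ₊₁ ≥ Mₙ an
  *alert period* opens with baseline Mₙ; if Mₙ₊ᵢ ≥ Mₙ for i = 1…k (k = 5)
  the rate is multiplied by α = 0.5 (l_new = l·α, 0 < α ≤ 1); a single epoch
  below the baseline cancels the alert.
* **Best-model pool.** After epoch n the weights enter the pool when
  Mₙ ≤ M_best ≤ M_threshold with Accuracy ≥ 0.95 and Loss ≤ 0.1
  (M_threshold = 0.005, which is exactly (1−0.95)·0.1, the supremum of
  monitors that can pass the gates). The pooled best model is reloaded into
  training every 10 epochs.

Preprocessing follows the standard chain: crop the black border by per-line
pixel summation, center-crop square, bilinear rescale to 299×299 (configurable),
and zero everything outside 95% of the fundus radius. Enhancement methods:
ORIGINAL, CLAHE (on the CIELAB luminance channel), LSACR (local-space-average-
color removal, `clip(4·I − 4·G_σ(I) + 128)`), and GRAY (Rec.601 luma).

Evaluation treats the left eye as the positive class: confusion matrix,
accuracy/sensitivity/specificity with Wilson 95% intervals, ROC by threshold
sweep over P1 (the left-eye probability) and AUC with a DeLong 95% interval.

## Worked example

```bash
# 60 labeled synthetic fundus photographs (256x192, black side bars)
fundus-laterality synth --n 60 --out data --seed 2 --sizes 256x192
# self-adaptive training run (tiny backbone at 64 px, 20 epochs)
fundus-laterality train --data data --out run --seed 0
```

prints `run complete: run`. The run directory holds the per-epoch curve
(`curve.csv`), the pooled best snapshot, and the evaluation report. The tail
of the curve shows the controller at work — learning rate reduced to 0.0125,
best-model saves, and a pool reload at the period boundary:

```
epoch,train_loss,val_loss,val_acc,monitor,lr,actions
...
19,0.06434980458021164,0.034322009564994094,1.0,0.0,0.0125,save
20,0.08514497206211091,0.03415195293779712,1.0,0.0,0.0125,save;reload
```

`report.json` for the 12-image validation split reads

```
accuracy 1.0, sensitivity 1.0, specificity 1.0, auc 1.0,
confusion {tp: 6, fn: 0, fp: 0, tn: 6}
```

i.e. every held-out image is assigned the correct eye. A CAM overlay for any
image (the heat map concentrates on the optic disc):

```bash
fundus-laterality cam --model run --image data/fundus_00000.png --out cam.png
# -> CAM (right) written to cam.png
```

The preprocessing-methods comparison (fixed learning rate, no self-adaptive
strategy, identical seeds across methods) is available as
`fundus-laterality compare-preproc --data data --out curves`.

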