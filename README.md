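# drgrade

Fine-grained grading of diabetic-retinopathy (DR) fundus images with an
attention-based, non-homologous bilinear convolutional classifier and a
complement-cross-entropy objective for long-tailed grade distributions.

DR grading is a fine-grained problem — the five ordinal grades (0 normal …
4 proliferative) differ only in subtle lesion statistics — and screening
datasets are severely imbalanced, with healthy eyes dominating. `drgrade`
combines three ingredients against this:

* **Non-homologous bilinear pooling.** Two architecturally different
  convolutional streams extract features x_s, y_s; the bilinear descriptor
  B(X) = Σ_s x_s y_sᵀ captures their second-order interactions and realises
  the polynomial kernel ⟨B(X),B(Y)⟩ = Σ_s Σ_u ⟨x_s,y_u⟩². The *compact*
  form replaces the c²-dimensional outer products with a d-dimensional
  Tensor Sketch, C(X) = Σ_s φ(x_s, y_s), an unbiased kernel estimate with
  d in the thousands.
* **Squeeze-and-excitation channel attention** per stream:
  y = σ(W₂·ReLU(W₁·GAP(x))) reweights feature channels in (0,1) so lesion-
  discriminative channels dominate before fusion.
* **Complement cross entropy (CCE).** The loss
  L = H(y,ŷ) + γ/(K−1)·C(y,ŷ), γ = −1, where C is the entropy of the
  incorrect-class distribution ŷ[j]/(1−ŷ[g]); maximising C flattens the
  incorrect-class mass and gives minority grades better learning signal
  without resampling or reweighting.

A seeded synthetic fundus generator (circular field, optic disc, vessels,
grade-monotone lesion densities, long-tailed class profile) makes the whole
pipeline — training, evaluation, ablation — runnable end to end on one CPU
with no external data. Everything trains on the package's own compact numpy
autodiff engine. See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
import drgrade as dg

# long-tailed 5-grade synthetic dataset: 1900 images, 32x32
spec = dg.SyntheticDatasetSpec(seed=0)
ds = dg.generate_dataset(spec)
train_ds, test_ds = dg.train_test_split(ds, 0.21, seed=0)
print(np.bincount(train_ds.labels), np.bincount(test_ds.labels))

# two distinct tiny backbones -> attention -> compact bilinear fusion (d=256)
model = dg.build_model(
    dg.BackboneSpec("tiny", output_channels=16),
    dg.BackboneSpec("tiny", output_channels=24, width=10),
    d=256, num_classes=5, seed=0,
)
cfg = dg.TrainConfig(epochs=20, seed=0, loss="cce")   # gamma = -1
model, history = dg.train(model, train_ds, cfg)
report = dg.evaluate(model, test_ds)
print(f"loss {history.train_loss.iloc[0]:.3f} -> {history.train_loss.iloc[-1]:.3f}")
print(f"accuracy {report.accuracy:.3f}  per-class recall {np.round(report.per_class_recall, 2)}")
```

prints

```
[1108  103  222   34   34] [295  27  59   9   9]
loss 0.754 -> 0.234
accuracy 0.852  per-class recall [1.   0.   0.76 0.   0.  ]
```

The label histograms show the long tail (majority base rate ≈ 0.74); the
training loss falls by more than half over 20 epochs; the trained model
clearly beats always-predict-grade-0, with most of the gain on the moderate
grade — at this scale the two rarest grades (34 training images each) are
still missed, which is exactly the regime the complement term targets at
full scale. Swapping
`loss="ce"` reruns the identical experiment under plain cross entropy for
comparison. The same workflow is available from the shell:

```bash
drgrade generate-data --seed 0 --out data/
drgrade train --data data/ --loss cce --seed 0 --checkpoint runs/model
drgrade evaluate --checkpoint runs/model --data data/
drgrade heatmap --checkpoint runs/model --image data/img_00000.png --out heat.png
drgrade ablate --grid grid.yaml --seeds 0,1,2 --out ablation.csv
```

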