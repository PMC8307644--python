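# Methods

## Problem and model

Diabetic retinopathy (DR) grading assigns a fundus photograph one of five
ordinal grades (0 normal … 4 proliferative). Two properties make it hard:
the task is *fine-grained* — adjacent grades differ only in subtle lesion
statistics, and intra-grade variation can exceed inter-grade variation —
and screening data are *severely long-tailed*, with healthy eyes dominating
and the severe grades rare.

`drgrade` addresses both with a two-stream bilinear classifier:

1. **Two non-homologous backbones.** Two architecturally different
   convolutional networks extract complementary feature maps from the same
   image. Three families are provided, all built on the package's own
   reverse-mode autodiff engine (`drgrade.autodiff`, a compact numpy tape
   machine): `tiny` (a three-layer strided stack), `resnet50` (a
   residual-style stack with identity shortcuts) and `densenet121` (a
   densely-connected stack with feature concatenation). The latter two are
   CPU-sized stacks in the residual and dense design idioms; no pretrained
   weights are distributed, and requesting them raises. A homologous
   (shared-weights) configuration is available for ablation.

2. **Channel attention per stream.** A squeeze-and-excitation gate:
   global average pooling to a per-channel summary v, then
   y = σ(W₂·ReLU(W₁·v)) with a bottleneck of width max(1, ⌊C/r⌋). The
   sigmoid weights in (0,1) rescale the channels. Defaults: reduction ratio
   r = 16, bias terms on, parameters *not* shared between streams. All
   three are configurable; none is forced by the mathematics, these are the
   common conventions.

3. **Compact bilinear fusion.** Exact bilinear pooling B(X) = Σ_s x_s y_sᵀ
   realises the second-order polynomial kernel ⟨B(X),B(Y)⟩ = Σ_s Σ_u
   ⟨x_s,y_u⟩² but is c²-dimensional. The compact form substitutes the
   Tensor Sketch: each stream's channel vector is Count-Sketched with
   frozen random hash/sign tables, the two sketches are circularly
   convolved (via FFT, O(d log d) per position), and positions are summed.
   The estimator is unbiased: E⟨φ(x,y), φ(x′,y′)⟩ = ⟨x,x′⟩⟨y,y′⟩. Sketch
   tables are drawn once from the model seed, never learned, and are
   regenerated from (C₁, C₂, d, seed) on checkpoint load. Library default
   d = 8192 (typical for full-scale backbones); the desk-scale model uses
   d = 256. The pooled descriptor gets signed-square-root and L2
   normalisation by default (switchable), the standard variance-stabilising
   step for bilinear features.

4. **Classifier.** A single affine map d → K followed by softmax.

When the two streams' grids differ (e.g. mixing families), both maps are
adaptively average-pooled to the elementwise-smaller grid before fusion —
parameter-free and deterministic.

## Complement cross entropy

For predicted distribution ŷ and true class g, the complement entropy is
the entropy of the incorrect-class distribution p_j = ŷ[j]/(1−ŷ[g]),
averaged over the batch; it is maximal, log(K−1), exactly when the
incorrect mass is uniform. Flattening that mass forces the true class —
also a rare one — to dominate the softmax, which is why the term helps
minority grades without reweighting or resampling. The combined objective

    L = H(y, ŷ) + γ/(K−1) · C(y, ŷ)

uses γ = −1 by default, so minimising L *maximises* the complement entropy;
the balance coefficient 1/(K−1) puts the two terms on one scale. Positive γ
is selectable for the literal additive form. Natural logarithms throughout.
Numerical conventions: ŷ[g] is clamped to ≤ 1−ε (ε = 1e−7) before the
1/(1−ŷ[g]) renormalisation; p·log p is continued by 0 at p = 0; samples
with no incorrect-class mass contribute 0. A focal-loss baseline
(α(1−ŷ[g])^γ_f, defaults α = 1, γ_f = 2) is included for comparisons.

## Synthetic study conditions

The generator emulates the structure of fundus screening data, not its
appearance: a dark circular field, one bright optic disc, 2–4 curved vessel
strokes, and three lesion archetypes — small dark dots (microaneurysm-like),
random-walk dark blobs (haemorrhage-like), bright patches (exudate-like) —
whose counts are Poisson with grade-monotone means

    grade:         0    1    2    3    4
    mean lesions:  0    3    9   17   28

split 2:0.5:0.5 (dots:blobs:patches) relative ratios per grade as given in
`DEFAULT_GRADE_PARAMS`. Grade 0 is exactly lesion-free. Default geometry is
32×32 RGB in [0,1]; lesion radii scale with image size. The default class
profile (1403, 130, 281, 43, 43) follows the long-tailed 65:6:13:2:2 shape
of real DR screening sets at total size 1900, so the default stratified
21% split yields ~1500 training and ~400 test images with a majority-class
base rate of ≈0.74. Determinism: image i is drawn from
`SeedSequence([dataset_seed, i])`, so datasets are bit-identical across
runs and images independent of generation order.

What the generator does *not* emulate: camera/illumination variation,
anatomical variability, lesion appearance detail, inter-grader label noise.
Passing tests therefore demonstrate that the architecture and losses behave
as designed on learnable grade-monotone statistics — not clinical-grade
performance on real fundus images.

## Training and evaluation

Mini-batch SGD with momentum 0.9, learning rate 0.01, batch size 32,
20 epochs — chosen once for the desk-scale model; training aborts with a
diagnostic on a non-finite loss. Images are zero-centered (−0.5) before the
backbones: with all-positive inputs the first-layer features are strongly
correlated and SGD reliably stalls in the predict-the-majority-grade
solution. Everything is seeded through `numpy.random.SeedSequence`; two
runs with the same config are bit-identical (pure single-threaded numpy,
no nondeterministic reductions).

Evaluation uses the mean-Jaccard accuracy convention, which for one label
and one argmax prediction per image (ties → lowest grade) equals the
exact-match fraction. Precision and recall are macro-averaged over the K
grades (macro rather than micro, so minority performance stays
visible), classes absent from both truth and prediction contribute 0, and
the reported F1 is the harmonic mean of the macro precision and macro
recall. Per-class recall and the full confusion matrix are always reported;
"minority recall" is the mean recall of the two rarest grades.

The ablation harness runs named single-axis variants (single-stream vs
bilinear, homologous vs non-homologous, backbone mix, CE vs focal vs CCE,
attention bottleneck) over a seed list and reports mean ± s.d. per metric.

## Numerical choices and limitations

* Signed-square-root gradient is regularised by ε = 1e−12 at the origin;
  L2 normalisation guards against zero norm the same way.
* Circular convolution and its gradient (a circular correlation) are both
  evaluated with real FFTs; odd sketch dimensions are handled exactly.
* Adaptive pooling windows follow the floor/ceil rule
  `[⌊iH/o⌋, ⌈(i+1)H/o⌉)`, matching the common deep-learning convention.
* Probability rows are validated to sum to 1 within 1e−6.
* At desk scale the two rarest grades have ~34 training images each; after
  20 epochs the tiny model often still predicts none of them, in which case
  both CE and CCE score zero minority recall — the CCE advantage shows up
  as at-least-as-good, not always strictly better, at this scale.
* The engine is float64 and single-threaded; it is sized for 32×32 desk
  experiments, not for training full-scale backbones.
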