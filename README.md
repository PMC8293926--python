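# hrcam — high-resolution class activation maps for pathology localization

`hrcam` localizes class-discriminative image regions from *image-level*
labels only.  It is aimed at medical-imaging workflows where a CNN
classifier works well but the question "which pixels drove the call?"
matters clinically — lesions on dermoscopy, fractures on radiographs,
subtle signal loss on MRI — and where the classic class-activation-map
answer is too coarse because the final convolutional layer is heavily
downsampled.

## The method

Let a CNN classifier with a global-average-pooling (GAP) + softmax head
be trained as usual (stage 1).  Pick k tapped layers
L = {l¹,…,lᵏ} — by default the last activation at each spatial
resolution ("pre-downsampling" layers) plus the final convolutional
output — with mᵢ feature maps at tap i.  Every feature map f is reduced
by GAP to a scalar, and the scalars are concatenated into a vector of
length

    N = Σᵢ₌₁ᵏ mᵢ .

Stage 2 freezes all convolutional parameters and trains a single dense
softmax layer on this vector by minimizing categorical cross-entropy
with Adam, yielding per-class weights Wᶜ = {w₁ᶜ,…,w_Nᶜ} over all N
feature maps.  The high-resolution class activation map is the weighted
sum of the (bilinearly upsampled, signed) feature maps

    A = Σᵢ₌₁ᴺ wᵢᶜ · up(fᵢ) ,

min-max normalized to [0,1].  Because shallow taps keep full spatial
resolution, A can resolve detail that a final-layer map cannot.  The
package also implements the two standard baselines behind the same
interface: Zhou's GAP-CAM (final layer, model's own head weights) and
Grad-CAM (gradient-weighted, rectified), plus a quantitative protocol
that scores every map against ground-truth masks by pixel-wise
sensitivity/specificity at thresholds 0.3/0.5/0.8 with paired t-tests.

A bundled simulator generates the two-class synthetic cohort used for
validation: a smooth phantom plus Gaussian noise (normative class)
versus the same phantom carrying localized blobs and a diffuse
correlated intensity field (abnormal class), with per-image ground-truth
masks.  Everything runs on a compact pure-numpy CNN engine
(`hrcam._nn`) whose backward passes are verified against finite
differences, so no deep-learning framework is required.

## Worked example

The reference experiment (600 training + 200 validation images, a
disjoint held-out test cohort; about eight minutes on one CPU core):

```python
import hrcam

# 1. simulate: 800 images (400/class), 64x64, with ground-truth masks
images = hrcam.generate_dataset(hrcam.SimulationConfig(n_per_class=400, seed=11))

# 2. stage 1: train the small CNN (GAP + softmax head), 75/25 split
model = hrcam.build_backbone("simple", (64, 64), class_count=2)
stage1 = model.fit(images, hrcam.TrainConfig(epochs=20,
                                             validation_fraction=0.25, seed=11))
print(stage1.summary())

# 3. stage 2: frozen-backbone head over concatenated GAP features
stage2 = hrcam.HRCAM(model).fit(images, hrcam.TrainConfig(
    epochs=50, validation_fraction=0.25, weight_decay=1e-4, seed=11))
print(stage2.summary())

# 4. explain held-out abnormal images at full resolution
test = hrcam.generate_dataset(hrcam.SimulationConfig(n_per_class=60, seed=10011))
abnormal = [im for im in test if im.label == 1]
amap = stage2.explain(abnormal[0], class_id=1)   # 64x64, values in [0,1]
```

The two summaries print:

```
CNN classifier (stage 1)
========================================
architecture:      simple
input size:        (64, 64)
classes:           2
taps (k):          3 ['relu1b', 'relu2b', 'relu3b']
epochs run:        20
final train loss:  0.0629
validation acc:    0.9950
validation AU-ROC: 1.0000
HR-CAM head (stage 2, frozen backbone)
============================================
taps (k):            3 ['relu1b', 'relu2b', 'relu3b']
concatenated N:      56
classes:             2
epochs run:          50
final val loss:      0.0463
head validation acc: 0.9950
  |w| share relu1b       0.473
  |w| share relu2b       0.356
  |w| share relu3b       0.171
```

The classifier clears the 95% accuracy / 0.99 AU-ROC bar, and the head
distributes its absolute-weight mass across all three resolutions (the
`|w| share` diagnostic) — the regime in which the fused map outresolves
the final-layer baseline.  Comparing methods against the ground-truth
masks of the 60 held-out abnormal images:

```python
comp = hrcam.evaluate_methods(
    abnormal,
    {"hrcam":   lambda im: stage2.explain(im, class_id=1),
     "zhou":    lambda im: hrcam.zhou_cam(model, im, class_id=1),
     "gradcam": lambda im: hrcam.grad_cam(model, im, class_id=1)})
print(comp.summary())                      # median/IQR per method x threshold
p, d = hrcam.compare_significance(comp, "hrcam", "zhou", "sensitivity", 0.5)
```

yields median pixel-wise sensitivity at threshold 0.5 of 0.186 (hrcam)
vs 0.166 (zhou) vs 0.034 (gradcam), with paired p-values 1.1e-3 and
8.1e-25 and positive mean differences (+0.016, +0.142) — the
multi-scale map detects more of the true abnormality at matched
thresholds.

The same pipeline is scriptable end to end:

```sh
hrcam run-all --seed 0 --out runs/demo         # simulate -> train -> evaluate
hrcam explain --checkpoint runs/demo/checkpoint \
              --image runs/demo/test_dataset --method hrcam --out runs/maps
```

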