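# Methods

## Model

The package implements weakly supervised localization by multi-scale
class-activation mapping.  Stage 1 is an ordinary CNN classifier ending
in global average pooling (GAP) and a C-way softmax.  Stage 2 freezes
every convolutional parameter, taps k intermediate activations
(default: the last activation at each spatial resolution, i.e. the
outputs feeding a pooling or strided convolution, plus the final
convolutional output), reduces each of the N = Σ mᵢ feature maps to its
GAP scalar, and fits a single dense softmax layer on the concatenated
vector by categorical cross-entropy with Adam.  The activation map for
class c is the signed weighted sum A = Σᵢ wᵢᶜ·up(fᵢ) over all N
feature maps, bilinearly upsampled to input resolution and min-max
normalized.  No rectification is applied to this map or to the
final-layer GAP-CAM baseline; rectification is part of Grad-CAM's
definition only.

Assumptions: the classifier is good enough that its discriminative
evidence is spatially meaningful; for a binary problem the head is a
2-way softmax (equivalent to a sigmoid for classification) so that an
explicit weight vector Wᶜ exists per class, which the map composition
requires.

## CNN engine

No deep-learning framework is assumed: `hrcam._nn` is a compact numpy
engine with convolution (im2col + matmul), ReLU, non-overlapping max
pooling, residual addition, GAP and dense layers arranged in a named
DAG.  Backward passes return gradients for parameters *and* for every
intermediate activation; the latter is what gradient-based mapping
needs.  Correctness is established by central finite-difference tests
over the full graph (tolerance 1e-7) rather than by construction.
Model inputs in [0,1] are centered by a fixed −0.5 offset so early
layers see a zero-mean signal; this is part of the model contract and
is applied identically at training and inference.

Two registry architectures exist: `simple` (three stages of two 3×3
convolutions, widths 8/16/32, for 64×64 desk-scale work) and
`resnet_small` (strided-convolution downsampling and identity skip
connections) which exercises tap enumeration on non-sequential graphs.
Deep user-supplied backbones fit the same `Network`/tap abstraction.

## Stage-2 optimization: standardized coordinates

Concatenated GAP features are badly scaled: post-ReLU activation
magnitudes shrink toward the input, so shallow-tap features are ~2
orders of magnitude smaller than final-tap features.  Optimizing the
head on raw features parks essentially all weight mass on the final
block and the fused map degenerates to the final-layer baseline.  The
head is therefore optimized in standardized coordinates (per-feature
mean/sd of the training split), with a small L2 penalty (1e-4,
standardized space) that keeps weights of dead or uninformative
features at zero; the affine change of variables is folded back into
the stored raw-feature weights afterwards, so the deployed head is
still exactly a linear layer on raw GAP values.  This is a
conditioning choice, not a change of model family.  The per-tap
absolute-weight share diagnostic (`layer_weight_distribution`) makes
the resulting regime visible: mass spread across taps means the fusion
is genuinely multi-scale; mass collapsed onto the final block means
the problem's evidence lives only in the deepest layer and the fused
map will mimic the final-layer CAM.

Stage-2 defaults: Adam, learning rate 1e-3, batch 32, at most 50
epochs, early stopping on validation loss (patience 5), head
initialized from N(0, 0.01²) with a fixed seed (not from the stage-1
head; the stage-1 final-layer weights would be a legitimate warm start
for the final block but would bias the comparison between taps).

## Bilinear upsampling convention

Corner-aligned pixel centers: output index u maps to source coordinate
u·(hᵢₙ−1)/(hₒᵤₜ−1); a 1×1 map broadcasts.  Different conventions shift
maps by up to one input pixel, so one is fixed and used everywhere
(map composition, both baselines).  Outputs are convex combinations of
inputs, hence bounded by the input range.  Weighted channel sums are
formed at native resolution and upsampled once per tap; by linearity
this equals per-channel upsampling (asserted against a brute-force
per-channel oracle at 1e-6).

## Degenerate cases and tie rules

* Min-max normalization of a constant map returns all zeros, so
  thresholding yields an empty detection.
* Binarization uses ≥ (ties count as detections).
* A rate with an empty denominator (no positive pixels for
  sensitivity, none negative for specificity) is recorded as missing
  and excluded from summaries, with a count kept.
* With a single tap equal to the final layer and the model's own head
  weights, the composed map is bit-identical to the GAP-CAM baseline
  (tested); at the final layer of a GAP-headed model, Grad-CAM's
  channel weights are wᶜ/(h·w), so its map equals the rectified
  GAP-CAM up to positive scale *at native resolution* (rectification
  and upsampling do not commute, so the identity is asserted before
  upsampling).
* Grad-CAM differentiates the pre-softmax class score (softmax
  gradients couple classes and vanish at saturation) and defaults to
  the last activation of the penultimate resolution stage.

## Synthetic cohort

The simulator emulates a two-class medical-imaging study in which the
ground truth is known by construction.  Both classes share a fixed
smooth phantom (radial bump on a diagonal gradient, intensities in
[0.15, 0.80]) plus i.i.d. Gaussian pixel noise (sd 0.05).  Abnormal
images additionally carry, on the noiseless phantom:

* **localized** disease: 1–3 additive circular blobs, radius 3–8 px,
  amplitude 0.25–0.5, tapering towards the rim but strictly positive
  on their support (so the support is exactly the disk);
* **diffuse** disease: a zero-mean spatially correlated field
  (Gaussian-smoothed white noise, correlation length 6 px, scaled so
  ~3 sd = 0.15) restricted to a random ellipse covering roughly a
  fifth to a half of the frame.

The ground-truth mask is exactly the support of the noiseless
perturbation, which makes pixel-wise evaluation well-posed; this is
assertable because the perturbation can be regenerated without noise.
One global seed drives a per-image seed sequence, so datasets of
different sizes share a prefix and every run is bit-reproducible.
Default image size is 64×64 and the reference experiment uses 400
images per class (600 training / 200 validation after a stratified 25%
split), a deliberately desk-scale rendition of the full 8,000-image
design the defaults extrapolate to.

What the simulator does *not* emulate: modality-specific appearance
(dermoscopy color, radiographic projection, MRI contrast), anatomical
variability between subjects, 3-D structure, or label noise.  Passing
results therefore demonstrate the correctness and the comparative
behaviour of the mapping machinery under controlled conditions, not
clinical performance.

## Evaluation protocol

Maps for held-out abnormal images (a seed stream disjoint from
training) are min-max normalized per image, binarized at thresholds
0.3/0.5/0.8, and scored against the mask by pixel-wise sensitivity and
specificity.  Methods are compared by per-cell median/IQR and by a
*paired* two-sided t-test on per-image rates — paired because the same
images underlie every method; an unpaired Welch option exists.
Normative images carry empty masks and are excluded.

## Known limitations

* The engine is single-threaded numpy; it is sized for desk-scale
  experiments (tens of seconds per training epoch on 600 64×64
  images), not for ImageNet-scale transfer learning.
* Seeded runs are bit-reproducible within an environment; across BLAS
  builds only metric-level (±0.01) reproducibility is promised.
* Absolute sensitivity values on the synthetic cohort are modest at
  threshold 0.5 (the diffuse component is low-contrast by design);
  the protocol's purpose is the *comparison* between methods at
  matched thresholds.
* The comparative advantage of the fused map is established at the
  reference scale (600 training images).  With much smaller cohorts
  stage-1 features are weaker and the weight-share regime — hence the
  method ranking — can differ; the weight-share diagnostic should be
  inspected before trusting the fused map on small data.
* The two-stage procedure requires freezing and a second optimization;
  the head is convex given frozen features, so this stage is cheap and
  stable, but the taps themselves are only as informative as stage-1
  training made them.
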