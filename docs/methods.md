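# Methods

## Scope and model

`actsign` implements a compact convolutional classifier for four-class
brain-MRI-style images and the machinery to compare nine scalar
activation functions inside it. The scientific object of interest is
the **rectified softsign** activation

    F(x) = x / (1 + x)   for x ≥ 0
    F(x) = 0             for x < 0,

a softsign whose negative branch is zeroed. It is identically equal to
`softsign(relu(x))` and to `relu(softsign(x))` (softsign preserves
sign), is bounded in [0, 1), saturates polynomially rather than
exponentially on the positive side, and has derivative `1/(1+x)²` for
x > 0 and 0 for x < 0. Like the ReLU family it silences negative
pre-activations; unlike ReLU it compresses large positive responses,
which interacts gently with batch normalization.

The other eight functions are the standard ReLU, Leaky ReLU, Clipped
ReLU, ELU, GELU, tanh, softsign and swish, all with closed-form
derivatives, applied elementwise over arrays of any rank.

## Network

The default architecture is a 16-layer stack (counting input, softmax
and the classification output as layers): input 224×224×3, then three
blocks of convolution → batch normalization → activation → max
pooling, then one fully connected layer to the class scores and a
softmax. The convolutions use 32, 64 and 32 filters of size 3×3 with
stride 3 and padding 1; the pools are 3×3 with stride 1 and padding 1
(a "same"-style pool that preserves spatial size). Under
`out = floor((in + 2p − k)/s) + 1` the spatial chain is
224 → 75 → 75 → 25 → 25 → 9 → 9, so the fully connected layer sees
9·9·32 = 2592 features and the per-layer learnable counts are

| layer   | formula              | count |
|---------|----------------------|-------|
| conv_1  | (3·3·3 + 1)·32       | 896   |
| bn_1    | 2·32                 | 64    |
| conv_2  | (3·3·32 + 1)·64      | 18496 |
| bn_2    | 2·64                 | 128   |
| conv_3  | (3·3·64 + 1)·32      | 18464 |
| bn_3    | 2·32                 | 64    |
| fc      | 4·2592 + 4           | 10372 |

for a total of 48 484. `audit_table2` recomputes every row from the
layer arithmetic and flags mismatches; the fully connected width is
always taken from shape inference, never hard-coded. Batch
normalization contributes only scale and offset as learnables; running
statistics are state. An alternative geometry reading (conv stride 2,
unpadded stride-2 pools) yields a 3×3×32 = 288-wide head; the audit
reports the computed width against 2592 explicitly, so any geometry
change is visible.

The padded stride-1 max pool is unusual but standard in mainstream
toolboxes ("same" pooling); it keeps the three pools from collapsing
the 75→25→9 chain and is the unique stride-consistent reading that
produces the 2592-wide head.

## Numerical engine

The layers (conv via im2col + BLAS matmul, batchnorm, elementwise
activation, overlapping max pool with −inf padding, dense) are
implemented directly on numpy float32 arrays with hand-written
backward passes, verified against central finite differences in the
test suite. Channel-last `(N, H, W, C)` layout throughout.

* Weight init: He fan-in normal for conv and dense (std √(2/fan_in)),
  batchnorm scale 1 / offset 0; all draws from a PCG64 generator
  seeded by the build seed, so two builds with one seed are
  bit-identical.
* Batchnorm: biased batch variance in training, running mean/var with
  momentum 0.1 for inference, ε = 1e-5.
* Derivative conventions at kinks: relu/clipped-relu/rectified
  softsign take the right-hand limit at 0 (all equal 1); clipped relu
  takes 0 at its ceiling.
* Softmax is max-shifted; cross-entropy clips probabilities at 1e-12.
* Optimizer: Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-8.

## Training protocol

Defaults mirror the reference experimental setup: Adam at learning
rate 1e-4, minibatch 64, epoch budget 64, categorical cross-entropy.
The loop shuffles with a generator seeded from the config, evaluates
the validation split each epoch, and returns the parameters of the
best-validation-accuracy epoch (a standard choice given a dedicated
10% validation split; the last-epoch alternative is recoverable from
the history). No learning-rate schedule, no augmentation, no dropout.

Splitting is stratified 70/10/20 per class (floor-based, each fraction
honored within one image per class), seeded and deterministic.
Class-name→index mapping is the alphabetical folder order. Images are
decoded to RGB, resized bilinearly, and scaled to [0, 1] by 1/255.

## Synthetic phantoms

`generate_phantoms` emulates the four-class task with deterministic,
seed-controlled geometry on an elliptical "brain" over a dark field:

* glioma — an irregular three-lobed bright blob in the interior;
* meningioma — a bright disc attached to the brain rim;
* notumor — background anatomy only (with a faint cosine shading so
  the class is not a constant image);
* pituitary — a small bright disc at the midline, low in the brain.

Lesion positions and radii jitter per image; additive Gaussian pixel
noise (default sd 0.05 on the [0, 1] scale) is clipped to range. The
generator can return the boolean lesion masks, which give Grad-CAM
localization checks an exact ground truth. Default 100 images per
class at 224×224 — a deliberately easy, linearly-well-separated task
(a nearest-centroid baseline on 8×8 thumbnails exceeds 90% accuracy).
Passing tests on phantoms therefore demonstrate that the pipeline
optimizes, generalizes on clean class structure, and localizes the
discriminative region; they say nothing about performance on real MRI,
where class differences are textural and acquisition varies.

### Desk-scale training configuration

The reference protocol (batch 64 on ~4 900 training images) performs
about 77 parameter updates per epoch. On the 280-image phantom
training split a batch of 64 would make only 5 updates per epoch, so
desk-scale runs keep the learning rate and optimizer unchanged and
shrink the batch to 4–8, restoring ~35–70 updates per epoch. With
batch 4 and 15 epochs the default network reaches >95% training and
>90% test accuracy on the standard phantom set; those sizes (400
images, 15 epochs) are the problem scale used by the acceptance
script and the end-to-end test.

## Metrics

Confusion matrices are tallied with rows = true class. Per-class
precision TP/(TP+FP) and recall TP/(TP+FN) come from the one-vs-rest
reduction; F1 is the harmonic mean 2PR/(P+R) (the "geometric mean"
phrasing that sometimes accompanies this formula in the literature is
a misnomer — the formula governs); the overall F1 is the macro
average. Undefined ratios (zero denominators) are reported as
undefined, never as 0. ROC curves sweep thresholds over unique scores
with ties grouped, and AUC is the trapezoidal area, equal to the
tie-corrected normalized Mann–Whitney U — the test suite asserts both
that identity and agreement with scikit-learn. Multiclass ROC is
one-vs-rest from the softmax scores, one curve per class. Percentages
are formatted to one decimal, halves rounding up.

## Grad-CAM

The heat map of class c is `relu(Σ_k α_k A_k)` where `A_k` are the
activation maps of the last (third) conv block's activation layer and
`α_k` is the spatial mean of ∂(pre-softmax score of c)/∂A_k. Gradients
are taken against pre-softmax scores because softmax gradients
saturate. The map is bilinearly upsampled to the input size and
min–max normalized to [0, 1]; an identically-zero rectified map is
returned as zeros with an explicit flag. The normalized map is
invariant to positive rescaling of the hooked activations, and a
hand-constructed linear model in the tests pins the map to a known
channel analytically.

### Localization behavior and its limits

Because the head is fully connected (not global-average-pooled), the
gradient of a class score with respect to the hooked maps is, up to
max-pool routing, the head's location-specific weight pattern — nearly
independent of the image. The channel weights α_k (spatial means of
that gradient) are therefore almost constant across inputs, and the
heat map localizes only insofar as the *channel activations* are
lesion-selective. On 224×224 phantoms this holds for the large
interior glioma blob (bounding-box heat density beats the outside on
essentially every test image) but not for the rim-attached meningioma
blob — which wanders the full rim, encouraging position-specific
rather than channel-specific encoding in the 2592-weight head — or the
small pituitary lesion. Training longer does not change this: a
diagnostic run to 100% training accuracy left meningioma at 3/10 and
pituitary at 0/10 bounding-box hits while glioma stayed 10/10. At
96×96, where the head has only 512 weights, the same check localizes
the meningioma class cleanly (`examples/gradcam_demo.py`). The
corresponding acceptance test asserts majority localization per lesion
class and documents this as the expected failure mode at full
resolution; the acceptance script reports the measured localization
fraction rather than asserting it.

## Sweep protocol

`run_sweep` trains all nine activations on the identical dataset,
split, initialization seed and budget, so the comparison is paired and
differences are attributable to the activation alone. The package
reports the resulting table but does not assert any ranking among
activations on phantoms: rankings are dataset-dependent, and the easy
synthetic task compresses differences that a harder textural task
would expose.

## Known limitations

* CPU-only, float32; practical up to a few hundred 224×224 images.
* Only the default architecture family (filter counts/geometry fixed,
  input size and class count configurable) is serializable to
  checkpoints.
* The phantom task's difficulty is controlled by noise_sd and lesion
  sizes but it remains far easier than real MRI; no texture, no
  acquisition variation, no class overlap.
* Batchnorm inference statistics come from momentum-0.1 running
  averages, so very short runs carry init bias in the running variance.
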