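# actsign

Activation-function experiments for a compact four-class brain-MRI
CNN, built around the **rectified softsign** nonlinearity

```
F(x) = x / (1 + x)    for x ≥ 0
F(x) = 0              for x < 0
```

— a softsign whose negative branch is zeroed, identically equal to
`softsign ∘ relu` and to `relu ∘ softsign`. It keeps the softsign's
bounded, polynomially saturating positive response (range [0, 1),
derivative `1/(1+x)²`) while gating negatives like a ReLU.

The package is aimed at people studying how the choice of elementwise
nonlinearity affects a small image classifier: it provides

* **activations** — nine functions (ReLU, Leaky ReLU, Clipped ReLU,
  ELU, GELU, tanh, softsign, swish, rectified softsign) with
  closed-form derivatives, applied elementwise to arrays of any rank;
* **architecture** — a declarative 16-layer CNN (three
  conv→batchnorm→activation→maxpool blocks of 32/64/32 3×3 filters,
  then a 4-way fully connected head) with shape inference and a
  learnable-parameter audit: conv layers count
  `(k·k·C_in + 1)·filters`, batchnorm `2·C`, the head `4·2592 + 4`,
  totalling 48 484;
* **data_io** — class-folder image loading
  (`root/<class_name>/*.jpg`), stratified seeded 70/10/20 splitting,
  and a deterministic 4-class synthetic **phantom generator** (brain
  ellipse + class-specific lesions with ground-truth masks) so nothing
  needs downloading;
* **training** — a seeded Adam loop (lr 1e-4, cross-entropy,
  best-validation checkpointing) on a small numpy layer engine with
  hand-written backprop;
* **metrics** — confusion matrix, per-class precision/recall/F1
  (harmonic), macro F1, one-vs-rest ROC with trapezoidal AUC;
* **explain** — Grad-CAM heat maps hooked at the last conv block;
* a thin CLI (`actsign run / sweep / audit-arch / generate-phantoms /
  explain`) over the library.

## Worked example

`examples/train_phantoms.py` generates 50 phantoms per class at 96×96
(noise sd 0.05), splits 70/10/20, trains the default network with the
rectified softsign for 20 epochs, and prints:

```
split sizes: train 140, val 20, test 40
final training accuracy: 97.9%
best validation accuracy: 90.0%

test confusion matrix (rows true, cols predicted):
[[10  0  0  0]
 [ 0  8  2  0]
 [ 0  1  9  0]
 [ 0  0  1  9]]

test accuracy: 90.0%
macro F1:      90.2%
```

Rows are true classes (glioma, meningioma, notumor, pituitary); the
diagonal holds correct predictions, so e.g. all 10 glioma test images
were recognized while meningioma was twice confused with notumor.
Accuracy is the diagonal sum over the total; macro F1 averages the
per-class harmonic means of precision and recall.

Other examples: `activations_demo.py` (the nine functions, their
derivatives, and the `softsign∘relu` identity), `audit_architecture.py`
(the parameter audit and per-layer shapes), `gradcam_demo.py` (heat-map
localization against the generator's ground-truth lesion masks),
`sweep_activations.py` (all nine activations on one shared split).

The same things are available from the shell, e.g.

```sh
actsign audit-arch
actsign generate-phantoms --out data/ --n-per-class 20 --seed 1
actsign run --config cfg.yaml --activation rectified_softsign --out runs/rs
```

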