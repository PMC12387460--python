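# dapnet

A dynamic-attentive pooling network for three-class CT-slice classification
(benign / malignant / normal), implemented entirely in NumPy — including a
small reverse-mode autodiff engine, convolution/batch-norm layers, and an
Adam optimizer (`dapnet.nn`), since no deep-learning framework is assumed.

Components:

- **`dapnet.covpool`** — second-order (covariance) pooling: spatial
  flattening, covariance with trace pre-normalization, the coupled
  Newton–Schulz matrix-square-root iteration (5 steps by default),
  post-compensation by the square root of the trace, and an
  eigendecomposition oracle used for verification.
- **`dapnet.attention`** — squeeze-and-excitation channel attention
  (global average pooling → two-layer bottleneck → sigmoid gains).
- **`dapnet.dfe`** — an adaptive feature-enhancement gate: a learned scalar
  α = sigmoid(mean(W·s + b)) selects or blends the second-order-pooling and
  SE branches (hard branching at threshold τ, or a soft convex blend), with
  an additive balance penalty λ·(α − 0.5)².
- **`dapnet.architecture`** — the assembled classifier on a ResNet50
  backbone (7×7 stem, bottleneck stages, two intermediate gates, SE block,
  covariance head), plus canonical ResNet50 / VGG16 reference builders and
  exact parameter counting; ablation flags (`use_se`, `use_sop`, `use_dfe`)
  and a `width_multiplier` for CPU-scale runs.
- **`dapnet.data`** — class-folder image loading (resize to 224, [0, 1]
  normalization), stratified 70/15/15 splitting (largest-remainder, seeded,
  optional group level), eight augmentation ops, and class balancing to
  target counts.
- **`dapnet.synthetic`** — a seeded three-class phantom generator
  (lung-field ellipses; smooth disc vs irregular textured blob) so the full
  pipeline is testable without any external data.
- **`dapnet.metrics`** — confusion matrix, one-vs-rest
  precision/recall/F1/accuracy, ROC/AUC by threshold sweep, stratified
  percentile bootstrap CIs, paired two-tailed t-test.
- **`dapnet.train`** — Adam + step-decay training loop (lr 0.001, ×0.1
  every 20 epochs), cross-entropy + gate penalty, best-validation
  checkpointing, and the augmented-train / raw-test generalization protocol.

## CLI

```sh
dapnet generate --out data/phantoms --n-per-class 50 --seed 1 --size 64
dapnet train --data data/phantoms --out runs/demo --width 0.25 --image-size 64 --epochs 5
dapnet eval --run runs/demo --data data/phantoms --image-size 64
dapnet params --arch resnet50 --classes 1000
```

`dapnet train` accepts a YAML config with `model:` (ModelConfig fields) and
`train:` (TrainConfig fields) sections; command-line flags override it.

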