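# Methods

This note records the modelling assumptions, conventions and deliberate
design choices behind `aquaqnet`, in the order the data flows through the
pipeline.

## Quantum core

The circuit simulator (`aquaqnet.circuits`) is an exact state-vector
simulator: amplitudes are complex128 vectors of length `2^n`, gates are
applied as sparse tensor contractions, and Pauli-Z expectations are
computed from exact probabilities. There is no shot sampling, no density
matrices and no noise channel — decoherence robustness is an argument for
*shallow* circuits, not something this package models. Qubit 0 is the most
significant bit of the amplitude index; this convention is fixed and used
consistently by the dense-unitary test oracles.

**Rotation triple.** Each strongly entangling layer applies a three-angle
rotation per qubit followed by a CNOT entangler. Two triples are in common
use, `R_z R_y R_z` and `R_x R_y R_z`; both give the same trainable count
(3 angles × n qubits × L layers). We default to `zyz` (the Euler
decomposition used by standard strongly-entangling-layer templates) and
expose `xyz` as a config switch (`rotation_order`). Triples are applied
lowest angle index first.

**Entangler topology.** Default is a ring, `CNOT(i → (i+1) mod n)` for all
`i` (two CNOTs for n = 2, none for n = 1); an open-chain `ladder` is
available. Both are config options because the two topologies differ only
in the single wrap-around gate at n = 4.

**Gradients.** All circuit gradients — with respect to the layer angles Θ
and with respect to the embedded inputs (needed to backpropagate into the
projection layer) — use the parameter-shift rule with shifts of ±π/2,
which is exact for gates generated by half Pauli operators. Property tests
compare against central finite differences (h = 1e-5) at 1e-6 and against
dense `2^n × 2^n` unitary oracles at 1e-9.

**Numerical conventions.** State normalisation is validated at 1e-9.
Batched evaluation (a `(B, 2^n)` amplitude array) is an implementation
convenience; results are independent of batch partitioning, which is
tested.

## Hybrid model and training

The trainable stack is: dense projection `c = tanh(Wz + b)` to one angle
per qubit → circuit → fusion `u = [c; q]` → dense(128) → batch-norm →
dropout → dense(64) → batch-norm → dropout → dense(n_classes) → softmax.
Only these tensors train; the backbone is frozen by construction (its
parameters live outside the optimizer and a byte-level test confirms they
never change).

Choices worth recording:

* **Head activation.** ReLU after each batch-norm, the conventional
  default for dense/BN/dropout blocks; `head_activation="linear"` is
  available. The nonlinearity of the model does not depend on it (tanh and
  the circuit are already nonlinear), but ReLU speeds convergence.
* **Batch norm.** Scale and shift are trainable (2 per feature — this is
  the convention under which the published per-layer counts are
  reproduced); running mean/variance are non-trainable state updated with
  momentum 0.99 and ε = 1e-3, excluded from all parameter totals. Biased
  (population) variance is used in both normalisation and the running
  update.
* **Dropout** is inverted dropout at rate 0.5: activations are rescaled at
  train time, inference is deterministic.
* **Feature standardization.** Pooled backbone features are z-scored per
  dimension using statistics of the training split only (constant features
  get unit scale). Pooled ReLU features are nonnegative with scales that
  vary by orders of magnitude across channels; without this step the
  projection layer starts deep in tanh's linear-but-tiny regime and the
  batch-norm running statistics chase a drifting activation scale, which
  destabilises inference-mode evaluation. The statistics are stored in the
  checkpoint and applied at prediction time. `standardize_features=False`
  disables it.
* **Initialisation.** Glorot-uniform dense weights, zero biases, unit/zero
  batch-norm scale/shift, circuit angles uniform in (0, 2π). All draws
  come from one seeded generator, so a single seed reproduces training
  bit for bit.
* **Optimisation.** Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), batch 32,
  global-norm gradient clipping at 1.0, reduce-on-plateau (factor 0.5,
  patience 2, monitoring validation loss), early stopping on validation
  loss with patience 5 and best-epoch weight restoration. The optimizer is
  a pluggable `step(params, grads)` contract (`register_optimizer`), so
  alternative adaptive schemes can be dropped in without touching the
  loop. Early stopping monitors validation loss because the plateau
  scheduler already does; the monitored quantity is the one degree of
  freedom the stopping rule needs.
* **Augmentation** (rotation ±30°, shift ±20%, shear ±20%, zoom ±20%,
  horizontal flip p = 0.5, nearest-edge fill) is a dataset-preparation
  operation: the workbench expands the training split before feature
  extraction when enabled. The fit loop itself consumes fixed
  pre-extracted features, which keeps the frozen-backbone extraction
  one-shot and the training trace exactly reproducible. Affine components
  compose in the fixed order rotate → shear → zoom → shift about the image
  centre; shift and zoom percentages are fractions of the image dimension
  and of unit scale.

## Parameter accounting

The ledger walks the architecture in order: frozen backbone
(adapter-declared count), GAP (0), dense `d→4` (`d·4 + 4`), circuit
(`3nL`), concat (0), dense/BN/dropout blocks, output dense. Backbone
counts are declared metadata on the profile adapters (ResNet50 23,588,096
frozen parameters, and the published pooled widths 2048/1280/1536/1920) —
the package never instantiates pretrained networks to account for them.
FLOPs use the coarse `2 × trainable parameters` heuristic throughout; an
exact MAC count is deliberately out of scope because every comparison this
toolkit makes is stated in terms of the heuristic.

## Metrics

Precision/recall/F-beta are one-vs-rest from the confusion matrix,
macro-averaged (micro available); a class with no predicted (true) samples
gets precision (recall) 0 with a warning. `Fβ = (1+β²)PR/(β²P + R)`,
reducing to `2PR/(P+R)` at β = 1. ROC/AUC is a one-vs-rest threshold sweep
(scikit-learn), cross-checked in tests against a brute-force
pairwise-ordering oracle with ties counted ½. Efficiency metrics:
`t_avg` = mean repetition wall time, throughput `N/t_avg`, latency
`1000·t_avg/N` ms/image. Training dynamics: E90 is the first 1-indexed
epoch with validation accuracy ≥ 90% of its maximum; σ_val is the
*population* (1/M) standard deviation over all executed epochs; ΔAcc is
train-minus-validation accuracy at the last *executed* epoch
(pre-restoration), since it is a statement about the end of the
optimisation trajectory, not about the restored best weights.

## Complexity-fitting plane

`g = Acc_train − Acc_val`; against a reference optimum `(O, g₀)` each model
maps to `X = P − O`, `Y = g − g₀`, with quadrants OER/OAR/UER/UAR and
points on either axis reported `ON_AXIS` rather than forced into a
quadrant. The reference is an explicit label or, by rule, the variant with
the lowest validation loss. Accuracies are accepted as fractions or
percents with an explicit unit flag and handled internally as fractions.

## Synthetic corpus

The generator emulates the *statistical structure* of a five-class
shrimp/prawn corpus under aquaculture imaging conditions: a blue-green
water background with a vertical light gradient, per-class parametric
motifs (curved segmented body chains with class-specific segment count,
curvature, size and hue; sparse bright blobs for larvae; a strongly
attenuated low-light variant, gain 0.3), smooth low-pass turbidity haze
(strength 0.25), additive Gaussian sensor noise (σ 0.03 of full scale) and
random pose jitter. Default 1084 images per class (≈ 5420 total) at
224×224, split 70/20/10 stratified with largest-remainder rounding
(priority train > val > test).

The motif parameters were calibrated so that the corpus satisfies two
properties by construction: a linear probe on frozen random-convolution
features separates the classes well, while mean gray intensity alone does
not separate the four non-dark classes (the low-light class is separable
by brightness by design). Both properties are asserted in the test suite.

What this corpus does **not** emulate: real shrimp morphology, occlusion,
specular highlights, compression artefacts, class imbalance or
photorealistic water optics. Passing the end-to-end tests therefore shows
that the architecture, gradients, training loop and evaluation stack are
correct and that the pipeline can learn a five-class underwater-style
problem — it says nothing about accuracy on real aquaculture imagery,
which additionally needs pretrained backbone weights and the curated
datasets.

## Problem sizes

The library-default corpus is 1084 images/class at 224×224. The end-to-end
experiments in the test suite and the acceptance script run a scaled-down
configuration chosen as a deliberate desk-scale design point: 200
images/class rendered at 64×64, the deterministic toy backbone (d = 16,
32×32 inputs), 4 qubits, 2 entangling layers, 20 epochs. At this scale a
full train/evaluate cycle takes tens of seconds on one CPU while
exercising every stage of the pipeline.

## Known limitations

* The functional backbone is a seeded random convolution stack; pretrained
  profiles are accounting metadata only, so headline accuracies obtained
  with real pretrained features are out of reach here by design.
* Exact expectations only: no shot noise, hardware noise or error
  mitigation, so conclusions about NISQ-device behaviour cannot be drawn.
* Per-sample circuit simulation scales as `O(L·n·2^n)`; the package is
  intended for few-qubit feature circuits (n ≤ ~10), not general quantum
  simulation.
* The alternative adaptive optimizer discussed alongside Adam in the
  hybrid-training literature is not shipped; the optimizer contract exists
  so one can be registered externally.
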