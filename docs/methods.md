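# Methods

`fedglioma` implements, at desk scale, a federated scheme for classifying
gliomas and their molecular subtypes from two-modality MR images: a 2D
two-stream attention-fusion CNN trained with a balanced focal loss under
dynamically regularized federated optimization, with unpaired
cycle-consistent domain mapping between imaging sites as preprocessing and
scan-level majority voting as postprocessing.  This note records the models,
the parameters that matter, the synthetic data the package is tested on, and
the design choices made where the design was genuinely open.

## The classification model

Each patient contributes 2D slices with two channels (a FLAIR-like and a
T1ce-like modality).  Channel *n* feeds stream *n* of the classifier; each
stream is seven 3×3 convolution + ReLU layers with 2× max-pool downsampling
at configured depths, ending in a global-average-pooled feature vector
*f*<sub>n</sub>.  The streams are fused by softmax attention over the scalar
scores *w*<sub>n</sub><sup>T</sup>*f*<sub>n</sub>,

  a<sub>s</sub> = exp(w<sub>s</sub><sup>T</sup>f<sub>s</sub>) / Σ<sub>n</sub> exp(w<sub>n</sub><sup>T</sup>f<sub>n</sub>),  f = Σ<sub>n</sub> a<sub>n</sub> f<sub>n</sub>,

stabilized by subtracting the per-sample maximum score.  The fused vector
passes through a learned affine-bilinear layer
z<sub>k</sub> = f<sup>T</sup>B<sub>k</sub>f + u<sub>k</sub><sup>T</sup>f + c<sub>k</sub>,
two fully connected ReLU layers and a softmax output.

The layer widths, pooling schedule and head sizes are configuration.  The
`paper-like` preset takes 128×128 inputs with widths (8,8,16,16,32,32,32)
and pooling after layers 2, 4 and 6; the `tiny` preset used by the test
suite and the synthetic benchmarks takes 32×32 inputs with widths
(2,4,4,8,8,8,8) and pooling after layers 1, 2 and 3 (early pooling shrinks
the costly full-resolution layers; the class signal in the benchmarks is
low-frequency and survives it).  No preset attempts to reproduce any
specific published parameter count.

All forward/backward passes are hand-written numpy (float32 for training,
float64 for gradient checks); there is no batch normalization, so the
forward pass of a slice is independent of the batch it arrives in, and
every analytic gradient is verified against central finite differences over
every parameter of a miniature configuration.

### Numerical choices that made the tiny networks trainable

Four choices matter at this scale and are deliberate:

* **Max pooling, not average pooling.**  The slice images are smooth;
  zero-mean kernels annihilate locally constant input, and averaging the
  near-uncorrelated residual shrinks activation scale ~2× per pooling
  stage.  Max pooling preserves scale.
* **A fixed feature gain (default 8) on the pooled stream features.**  Even
  with max pooling, He-initialized stacks attenuate smooth, low-contrast
  input; without compensation the quadratic head sees ~10⁻² features and
  produces vanishing logits.
* **An affine-bilinear head.**  A pure quadratic form f<sup>T</sup>B<sub>k</sub>f
  has gradient ∝ ‖f‖, which vanishes exactly where training starts; the
  added linear and bias terms keep gradients alive at small activations.
* **Zero-initialized output layer and gradient-norm clipping (default 1.0).**
  Every class starts at probability ½ (a saturated softmax start
  destabilizes focal training, whose gradients are small near saturation),
  and occasional exploding steps through the quadratic head are clipped.

## Loss

With p ∈ {0,1} the label, q = 1−p, and p̂ the predicted positive-class
probability (q̂ = 1−p̂):

  L = −[ β q̂^γ p log p̂ + (1−β) p̂^γ q log q̂ ]

γ ≥ 0 focuses training on hard examples (γ=0 with β=0.5 is exactly half the
binary cross-entropy — an analytic identity the suite asserts on a grid);
β ∈ [0,1] weights the positive-class term.  Defaults are β=0.25, γ=2.
β's orientation relative to actual class frequencies is ambiguous in
general; on the synthetic imbalance benchmark, where the positive class is
the 10% minority, the benchmark uses β=0.9 (up-weighting the rare class
toward the majority fraction, the standard balanced-focal recipe).  Natural
log, mean batch reduction, probabilities clamped to [10⁻⁷, 1−10⁻⁷].

## Federated optimization

Each communication round t broadcasts central weights w_c, every client runs
K local epochs of minibatch SGD, and the server aggregates.  The
dynamically regularized algorithm uses the local update direction

  g = ∇L(w) + λ_wd·w − c_i + α(w − w_c),   w ← w − η g,

with gradient-correction state c_i ← c_i − α(w_i − w_c) after each round,
and the server accumulator

  h ← h + (1/N)(w_c − w̄),   w_c ← w̄ − h,   w̄ = (1/N) Σ w_i.

A sign-flipped variant of the local direction
(−∇L − c_i − α(w_c − w)) is retained behind `FLConfig.eq4_as_printed`
for auditability; it ascends the loss at α=0 and is off by default.  The
server's h-update carries no α factor by design.  FedAvg is plain local SGD
with sample-size-weighted averaging; the central-learning (CL) reference
trains the identical architecture on pooled data.  All clients participate
every round; clients are simulated sequentially with independent
generators keyed by the client's rank in sorted-id order, so results do not
depend on supply order, and a single-client FedAvg run is bit-identical to
the matched central run.

Defaults follow the study setup: T=50 rounds, K=5 local epochs, batch 50,
η=0.01, α=0.01, weight decay 0.001 (federated) / 0.0001 (central), no
learning-rate decay across rounds.  The synthetic benchmarks run hotter —
η=0.05, α=0.1 — because the focal loss's modulating factor shrinks
gradients several-fold and the tiny networks tolerate (and need) larger
steps; these are calibrations of scale, not of outcome.

`convergence_round(history, delta)` returns the first round from which the
pooled test accuracy stays within `delta` of its final value (default 0.02;
the benchmarks detect convergence with a 5-point band because desk-scale
curves fluctuate by a few points between rounds).  Evaluation always uses
the final-round model.

## Domain mapping

Unpaired, cycle-consistent intensity harmonization between two sites'
preprocessed slices.  Generators are residual 3-layer 3×3 conv nets
(output = input + learned correction, so the initial map is near-identity);
discriminators are small conv nets with a scalar score.  Least-squares GAN
terms, L1 cycle loss with λ=10, Adam training; the total objective is

  L = L_GAN(to_target, D_target) + L_GAN(to_source, D_source) + λ L_cyc.

Only the source site is mapped; the target site passes through unchanged.
Mapped images are clipped to [0,1]; labels and provenance are untouched by
construction.

## Preprocessing

Per patient: the five slices with the largest tumor cross-section from each
of the three views (ties to the lower index — a deterministic rule chosen
for reproducibility), 15 slices per patient; pixels outside the tumor mask
attenuated to exactly 1/3; resize to a square grid; min-max normalization
to [0,1] per slice and channel (scope chosen as per-slice: it removes only
part of the inter-site brightness difference, which is precisely why domain
mapping remains useful).  A constant slice maps to all zeros.  Training
augmentation is a horizontal flip (p=0.5) and a rotation uniform in ±10°
(bilinear, zero padding), never applied at test time; the synthetic
benchmarks leave it off — their lesions already vary and the rotation's
zero-padded corners perturb the background statistic that carries the
class signal.

## Scan-level decision and evaluation

A patient is positive iff strictly more than half of their M slice
predictions (threshold 0.5 on the class-1 probability) are positive; even-M
ties resolve to the negative class, and with the standard M=15 ties cannot
occur.  Metrics are accuracy, sensitivity = TP/(TP+FN) and specificity =
TN/(FP+TN) with class 1 (the IDH-mutation/LGG analogue) positive; a zero
denominator yields an explicit "undefined", never a silent 0.  Repeated
runs report mean and sample (n−1) standard deviation; slice-level accuracy
pools slices across patients.

## Synthetic cohorts

The generator emulates the statistical structure multi-hospital glioma
cohorts impose on the scheme — per-site class imbalance, a learnable
class signal, and scanner-induced intensity shift — with none of the
anatomy: 32³ volumes, spherical lesions (radius 4–6 voxels, guaranteeing
≥5 tumor-bearing slices per axis) with smoothed-noise texture on a smooth
background.  Classes differ in mean lesion intensity (0.30 vs 0.75) and
texture granularity; the FLAIR-analogue shows the full lesion, the
T1ce-analogue emphasizes the rim, so the two streams carry complementary
signal.  Site shift is the monotone transform v → gain·v^γ + offset plus
voxel noise.  The intensity separation is calibrated so the slice-level
task after per-slice min-max normalization is linearly separable (absolute
intensity does not survive normalization; what remains is the
background-to-lesion contrast ratio, and radius variation confounds
area-based summaries).

What the generator does **not** emulate: anatomy, bias fields,
registration artifacts, nonspherical lesion geometry, modality
misregistration, or realistic MR noise spectra.  Passing benchmarks
therefore show the *algorithms* behave as designed under the assumed
statistical structure; they say nothing about accuracy on real MRI.

## Benchmark study conditions

All benchmarks use the tiny preset, 32×32 slices, 15 slices/patient, and
are repeated over independently seeded repetitions (5 in the test suite, 3
in `scripts/acceptance.py`), each repetition regenerating, re-partitioning
and retraining; comparisons use medians.

* **IID separable** — two sites, 10+10 patients each, stratified 80/20
  split, T=30: both algorithms must reach ≥0.95 pooled slice accuracy.
* **Label skew** — two clients with 8/2 vs 2/8 training patients (at 15
  slices per patient, a one-patient minority class is degenerate — its
  test behavior is luck — so 2 minority patients is the smallest honest
  skew), T=30: the dynamically regularized algorithm should converge no
  later than FedAvg.
* **Imbalance** — 18/2 training patients per client with overlapping class
  appearance (lesion means 0.42 vs 0.58, noise 0.04): class weighting can
  only shift the sensitivity/specificity tradeoff when classes overlap, so
  the overlap is the point.  Focal (β=0.9, γ=2) vs cross-entropy minority
  sensitivity, T=15.
* **Scan-level voting** — 10+10-patient sites, T=15: patient-level vs
  pooled slice-level accuracy.
* **Domain mapping** — 8+8-patient sites, a strong injected shift
  (gain 0.6, offset 0.05, γ=1.8) on the source site, mapper trained 25
  epochs, T=20 FedAvg with cross-entropy (the contrast is clearest without
  the dynamic regularizer, which already absorbs part of the heterogeneity,
  and the faster loss keeps the short-horizon comparison about the data).

## Known limitations

* Pure-numpy training limits problem sizes to tens of patients and 32×32
  slices; the `paper-like` preset builds and runs but is not benchmarked.
* The benchmark contrasts are directional medians over few repetitions;
  individual seeds can invert them.
* The toy mapper harmonizes global intensity statistics only; it has no
  capacity for spatially structured scanner artifacts.
* Focal-loss training is slow on balanced, easy data (its modulating
  factor suppresses exactly the gradients that drive early learning); the
  benchmarks compensate with the hotter learning rate noted above.
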