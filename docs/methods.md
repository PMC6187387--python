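# Methods

## Problem and pipeline

The package classifies four horse-riding gaits (walk, sitting trot, rising
trot, canter) from 8-channel rider-motion time series: hip height, backbone
angle, left/right elbow and knee angles, and elbow/knee distances. The
pipeline is signal compression (wavelet packets) → windowed statistical
features → stacked auto-encoder (SAE) classifiers → probability-level
ensemble fusion → confusion-matrix evaluation. All numbered defaults below
are the package's fixed study configuration; everything is overridable
through `TrainConfig` / `PipelineConfig`.

## Synthetic gait generator

Expert-rider motion-capture data is private, so `gaitstack.synth` emulates
its structure. Each channel of a gait is a harmonic series around the
channel midpoint,

    c(t) = mid + half_span · Σ_k w_k sin(2π (k+1) t / P + φ_c) / Σ_k w_k
           + ε_t,  ε_t ~ N(0, σ_c²),

so the noiseless signal is exactly bounded by the channel's (min, max).

Parameters and defaults:

- **Amplitude bounds.** Rising trot and canter use the expert-rider reference
  min/max table (cm for hip height and distances, degrees for angles). The
  printed canter elbow-distance pair is transposed (min > max) and is stored
  swapped. Left/right joint angles share the printed bounds and are set in
  antiphase (π phase offset). Walk and sitting trot are not tabulated: walk
  keeps the rising-trot midpoints with 35 % of the span (capped by the
  canter span per channel, so walk always has the smallest amplitudes);
  sitting trot sits 5 % of span below the midpoint with 60 % of the span.
  These constants were fixed once so the four classes overlap but remain
  distinguishable.
- **Periods** (frames; no wall-clock rate is modelled): walk 120, sitting
  trot 70, rising trot 60, canter 45 — canter's cycle is the shortest and
  walk's the longest, as in real strides. The values themselves are
  conventional, not measured.
- **Harmonics** w = (1.0, 0.35, 0.15): a dominant fundamental with two
  weaker overtones, giving periodic but non-sinusoidal traces.
- **Noise** is additive i.i.d. Gaussian per channel with σ_c = 5 % of the
  channel half-span.

Per-gait seeds are spawned from the master seed via
`numpy.random.SeedSequence`, making datasets bit-reproducible.

What the generator does **not** emulate: within-gait tempo drift, transients
between gaits, horse- and rider-specific idiosyncrasies, cross-channel
phase coupling beyond fixed offsets, and non-Gaussian sensor artifacts.
Under these idealized conditions the four classes are cleanly separable, and
the benchmark accuracies (≈100 %) reflect that; passing tests demonstrate
the pipeline's correctness and the expected ordering of methods, not
field performance on real riders.

## Wavelet-packet compression

`gaitstack.wavelet` implements the orthogonal analysis filter bank
directly: one packet step is periodized correlation with the scaling filter
h (approximation) and its quadrature mirror g (detail), downsampled by two.
Choices:

- **Boundary handling is periodization** so lengths halve exactly
  (ceil(n/2) per level); 49,000 → 12,250 at level 2. Symmetric or zero
  padding would inflate lengths.
- **Phase convention**: `approx[m] = Σ_k h[k] x[(2m + k + 1 − L/2) mod n]`
  for a length-L filter, odd-length inputs extended by repeating the last
  sample. This matches PyWavelets' `periodization` mode, which the test
  suite uses as the independent reference (100 random signals, every node,
  1e−8 relative).
- **Default filter db2** (shortest Daubechies filter with one vanishing
  moment beyond Haar); Haar is also registered. The mother wavelet is a
  config knob — classification quality is driven by the low-pass trend, not
  the specific short orthogonal filter.
- The pipeline keeps only node (2, 0) by default (level is configurable);
  detail nodes are computed but unused — high-frequency rider motion is
  sparse and uninformative for gait class.

## Features and scaling

Non-overlapping windows of 20 samples; five statistics per channel per
window (mean, max, min, variance, std), channel-major column order.
Non-overlap is the reading consistent with 12,000 samples/gait → 600
windows/gait → a 2400-row table. **Variance is the population variance**
(÷ n), and the std column is its square root; tests pin this convention.
Trailing partial windows are dropped.

Features are min-max scaled to [0, 1] with training-split statistics only
(sigmoid decoders need bounded reconstruction targets); constant training
columns map to 0, and test values may fall slightly outside [0, 1].

## Auto-encoder and stacking

A single auto-encoder is z = σ(Wx + b), x′ = σ(W′z + b′) with untied
weights, trained by **full-batch** gradient descent (new = old − η·grad).
Full batch keeps training deterministic and matches the plain
gradient-descent update rule; there is no momentum, minibatching or
adaptive optimizer.

- **Objective**: per-sample squared error ‖x − x′‖² (cross-entropy
  available; reconstruction layers default to squared error, the supervised
  stage uses softmax cross-entropy), averaged over the batch, plus an L2
  penalty λ(‖W‖² + ‖W′‖²) with λ = 1e−4 by default, plus an optional KL
  sparsity penalty Σ_j KL(ρ ‖ ρ̂_j) on mean hidden activations (off by
  default; ρ = 0.05 when on).
- **Initialization**: uniform(−r, r), r = √(6/(fan_in + fan_out)); biases
  zero. η = 0.1 constant by default; max 3000 epochs; early stop when
  successive objective values differ by < 1e−9.
- Cross-entropy reconstructions are clipped at 1e−12 before logs.
- Divergence (non-finite loss, possible with large η through the L2 term)
  raises rather than returning garbage.
- **Gradient correctness** is established by central finite differences
  (h = 1e−6) on every parameter block, both losses, with and without
  penalties; the check uses a denominator floor of 1e−3, which keeps it
  above the ~1e−9 cancellation noise of double-precision differences.

Stacking is greedy: auto-encoder k is trained on the codes of k−1; decoder
halves are then discarded. The softmax head starts at zero (uniform
probabilities), and fine-tuning runs full-batch gradient descent on softmax
cross-entropy through head and all encoder layers jointly, with the same L2
coefficient on encoder and head weights (biases unpenalized). The same
finite-difference gate covers the full stacked objective.

## Ensemble fusion

Members are trained independently on the same training rows; diversity
comes only from hidden-size layouts and derived seeds (member i uses
seed + 7919·(i+1)). Study layouts: two members (46) and (15); three members
(30), (20), (10). The sum rule averages probability vectors; the product
rule multiplies them elementwise in log space and renormalizes — the
renormalization keeps reported values on the probability simplex and leaves
the argmax decision unchanged. A sample whose product is zero in every
class is rejected as degenerate. Ties at the argmax break toward the lowest
class index.

## Evaluation

Splits are stratified 50:50 within class (shuffle with the given seed; odd
counts put the extra row in train). The report exposes the confusion matrix
(rows = truth), overall accuracy trace/n (also as a percent), and per-class
one-vs-rest accuracy (TP + TN)/(TP + TN + FP + FN). The two accuracy
notions differ: one-vs-rest credits true negatives, so its per-class values
exceed overall accuracy whenever errors are off-diagonal; both are emitted.

## Problem sizes used in tests and the acceptance script

Shape checks run at full scale (49,000-frame channels; 48,000 raw
frames/gait → 12,000 compressed → the 2400 × 40 table and 1200-row test
split). The classification benchmark uses 12,000 raw frames per gait
(150 windows/gait after compression), the full 3000-epoch schedule, and
5 seeds, comparing the two-member sum-rule ensemble against a single
hidden-40 SAE. Unit tests use reduced frame counts and epochs; the
reduced-scale runs exercise identical code paths.

## Known limitations

- Synthetic separability: the default benchmark saturates near 100 %
  accuracy; it validates mechanics and method ordering, not real-world
  difficulty (see the generator's non-goals above).
- Full-batch gradient descent with a constant learning rate is deliberately
  simple; it is not a competitive optimizer for large problems.
- Only Haar and db2 filters are registered; longer wavelets would need
  their coefficients added (the periodization machinery is length-generic).
- The product rule can be numerically extreme when members are
  overconfident; probabilities are clipped only through the log-space
  computation, not recalibrated.
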