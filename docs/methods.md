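# Methods

## Problem and pipeline

`fatiguefuse` classifies the fatigue state of an exercising person —
`Relax`, `Transition`, or `Tired` — from two wearable modalities
recorded simultaneously: 6-channel surface electromyography (sEMG,
2000 Hz) and 18-channel accelerometry (ACC, 20 Hz). The pipeline is

1. band-pass the sEMG to 20–500 Hz (zero-phase 4th-order Butterworth),
   optionally notch 50 Hz mains, and cut both modalities into aligned
   non-overlapping 10-s epochs;
2. compute 42 features per sEMG channel and 6 per ACC channel, and
   fuse the 6×42 sEMG map with the transposed 18×6 ACC map into a 6×60
   grid per epoch;
3. classify the fused grid with an 8-layer 1-D CNN carrying attention
   at three granularities: an amplitude-envelope re-weighting of the
   input rows, squeeze-and-excitation (SENet) channel gates after the
   first seven convolutions, and parameter-free simAM neuron weighting
   after the last one;
4. evaluate with stratified 10-fold cross-validation and a
   pseudo-artifact protocol that deliberately cross-contaminates the
   modalities.

## Feature suite

Per sEMG channel, in fixed column order: 8 wavelet marginals
(Daubechies-2, 7-level decomposition; marginal = Σ|coefficient| per
subband, approximation first, then details coarse-to-fine), a 20-bin
amplitude histogram over μ±3σ (out-of-range samples clipped into the
end bins; frequencies, so the row is amplitude-scale comparable), RMS,
zero crossings (ZC), slope sign changes (SSC), waveform length (WL),
mean absolute value (MAV), the two-segment MAV slope (MAVS), Willison
amplitude (WAMP), 5 Yule–Walker autoregressive coefficients, mean
frequency (MNF) and power-spectrum ratio (PSR) from a Hann-window
periodogram (PSR band: spectral peak ±10 Hz). Per ACC channel: MEAN,
population VAR, RMS, WL, MAV, MAVS.

Defaults that are conventions rather than necessities: ZC/SSC
thresholds 0; WAMP threshold 0.1× the channel's standard deviation
(it must scale with amplitude to be meaningful across gains); AR order
5, which is what makes the per-channel count come to 42 together with
the 8+20 wavelet/histogram columns; the population (1/N) standard
deviation everywhere. Features are computed on band-passed but
unstandardized epochs; standardization happens later, inside the
classifier's input stage.

A zero-power channel makes MNF/PSR undefined; they are returned as 0
with a warning. A constant channel makes the AR fit degenerate and
raises. The fusion transpose places ACC feature *i* (across all 18
channels) in row *i* of the fused map, i.e. `fused[i, 42+j] =
acc_map[j, i]`; this is a bookkeeping convention of the fusion, not a
physiological pairing.

## Attention mechanisms

**Envelope input attention (LFAM).** Each row of the fused map is
standardized (z-score, population convention), its amplitude envelope
A(t) is taken as the modulus of the analytic signal (frequency-domain
Hilbert construction, no edge tapering — tests use interior samples),
and the row is multiplied by A(t)/mean(A(t)). Dividing by the mean
envelope is what makes the weights hover near 1 for stationary rows:
the raw envelope of a standardized signal does not do that by itself.
Constant rows standardize to zero and stay zero.

**SENet channel gates.** After each of the first seven convolutions,
channels are squeezed by global average pooling and passed through a
bias-free bottleneck `sigmoid(W2·relu(W1·x_sq))` whose output rescales
the channels. The reduced width is `filters // r` with `r = 16` by
default, giving `2·filters·(filters//r)` trainable parameters per
block — 1200 for 100 filters. Note that 16 does not divide 100, so the
idealized count `2·filters²/r` (1250) is not realizable with integer
units; the floor rule is the standard practice and is what the
parameter audit asserts.

**simAM neuron weighting.** After the final convolution every neuron
q is scored by the closed-form minimum of a linear-separability
energy, `e*(q) = 4(σ²+λ)/((q−μ)² + 2σ² + 2λ)`, with μ and σ² the
pooled mean and population variance of the channel and λ = 1e-4. The
output is `sigmoid(1/e*) ⊙ X`; weights lie in (0.5, 1) and grow with a
neuron's distance from its channel mean. The mechanism adds zero
trainable parameters. A neuron at the channel mean has energy exactly
2 for any λ and σ². The test oracle minimizes the underlying
two-parameter objective numerically (Nelder–Mead) with the same pooled
statistics and agrees with the closed form to ≲1e-12.

## Classifier and training

The network is built in NumPy with hand-written reverse-mode gradients
(`fatiguefuse.nn`): 8 one-dimensional convolutions (100 filters,
kernel 2, stride 1, right-zero padding so length 60 is preserved; no
pooling anywhere), ReLU activations, the attention stages above,
flatten, dense(16, ReLU), dense(3, softmax). The 6 fused rows are the
input channels of the first convolution. The gradient implementation
is verified against central finite differences to ~1e-6 relative
error in float64. Two deliberate approximations:

- simAM's attention weights are treated as constants during the
  backward pass (gradients flow through the multiplicative path only);
  differentiating through the energy map is possible but adds cost
  without changing what the mechanism contributes;
- arithmetic is float32 for speed; training is bit-deterministic for a
  fixed seed on a fixed BLAS.

Before the network, each of the 360 feature cells is standardized
using training-set statistics (a constant cell maps to zero); without
this, the heterogeneous feature scales (MNF ~100 Hz next to histogram
frequencies ~0.05) make the attention-free baseline untrainable and
the comparison meaningless. The envelope attention, when enabled, is
applied after this standardization.

Optimizer: Adam, learning rate 1e-3, batch 32, at most 100 epochs with
early stopping (patience 8) on the loss of a stratified 10% validation
split, best-epoch weights restored. These optimizer settings are the
package's own defaults. Evaluation protocols in the test-suite and the
acceptance script cap training at 4–10 epochs without early stopping:
the synthetic classes are widely separated and converge within a few
epochs, so longer schedules change nothing but runtime.

Cross-validation uses seeded stratified k-fold splitting
(scikit-learn); every example is validated exactly once, each fold
trains a freshly initialized model (seed = base seed + fold index),
and the aggregate is the mean ± sd of fold metrics.

## Synthetic data: what it emulates, and what it does not

The generator encodes the two robust directions of fatigue
physiology: the sEMG mean power frequency falls (slowing fiber
conduction) while amplitude rises (more fibers recruited), and limb
motion becomes more variable around a fixed pedalling cadence. Per
class: sEMG = unit-RMS band-pass-shaped Gaussian noise (4th-order
Butterworth, 60 Hz band centered at 120/95/70 Hz for
Relax/Transition/Tired) scaled by gains 1.0/1.3/1.7, plus a 0.05
broadband noise floor; ACC = unit sinusoid at 1.2 Hz (≈72 rpm cycling
cadence, random phase per channel per epoch) plus white tremor of
amplitude 0.1/0.2/0.4 and the same noise floor. The 18 ACC channels
are treated as two virtual 9-axis IMUs and differ only by phase and
noise. All parameters are configurable; class centers must decrease
and gains/tremor increase across the three states.

Seeding: a master seed plus the epoch index gives each epoch's seed;
each (seed, state, modality) tuple derives an independent stream, so
any record is regenerable in isolation and identical configurations
are bit-identical.

These signals are deliberately easy: classes are separable by design,
so cross-validated accuracies near 100% on them say that the pipeline
is wired correctly and that attention does not hurt — not that the
model would reach any particular accuracy on human recordings, which
carry inter-subject variability, nonstationarity within epochs,
electrode artifacts and label noise that the generator does not
emulate. Directional claims (MNF falls, variance rises, contamination
degrades metrics monotonically in expectation) are the meaningful
transferable checks.

## Pseudo-artifact protocol

Seven conditions: clean, and cross-modal contamination at weights
0.1/0.2/0.5 in each direction. Contaminating sEMG: each ACC channel is
upsampled to 2000 Hz by linear interpolation, standardized, averaged
in groups of three consecutive channels, and added (× weight) to the
matching sEMG channel. Contaminating ACC: each sEMG channel is
anti-alias filtered and decimated to 20 Hz (polyphase resampling),
standardized, mapped cyclically onto the 18 ACC channels, and added
(× weight). Weight 0 returns the inputs bit-identically. The weight is
a single scalar per condition applied to all axes; feature extraction
and cross-validation are re-run from scratch under every condition.
Reported per-class metrics are one-vs-rest accuracy, precision,
recall and F1 (F1 = 0 by convention when precision + recall = 0);
support-weighted recall equals overall multiclass accuracy exactly.

## Problem sizes used in the shipped evaluations

The test-suite's ablation check uses the generator defaults (100
epochs per class, master seed 42) with 10-fold cross-validation of the
full-attention and attention-free models, averaged over 3 fold seeds,
training 10 epochs per fold. The robustness check uses 20 epochs per
class, 5 folds and 4 training epochs. `scripts/acceptance.py` uses 30
epochs per class, 5 folds and 10 training epochs for the ablation
comparison and 3 folds / 5 epochs for the contamination conditions.
These sizes are the package's chosen desk-scale defaults; all are
configurable upward.

## Known limitations

- The synthetic classes are far more separable than human data; see
  above for what passing tests do and do not establish.
- The simAM backward pass is approximate (stop-gradient on weights).
- No learned version of the envelope attention; no 2-D/spatial
  attention variants; no feature selection.
- The ACC channel semantics (which axis of which IMU) are nominal; the
  18-channel layout is a convention, and the grouped averaging in the
  contamination protocol follows that convention rather than any
  anatomical pairing.
- Streaming/online use is out of scope: filtering is zero-phase
  (non-causal) and epochs are processed in batch.
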