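# fatiguefuse

Motion-fatigue recognition from fused surface-EMG and accelerometer
signals, for researchers and engineers building wearable fatigue
monitors. The package classifies 10-second activity epochs into
`Relax` / `Transition` / `Tired` using a feature-level fusion of
6-channel sEMG (2000 Hz) and 18-channel accelerometry (20 Hz) and a
small 1-D CNN with attention at three granularities.

## Method

Each epoch yields a fused feature map **F** ∈ ℝ^{6×60}: 42 features
per sEMG channel (wavelet marginals, amplitude histogram, RMS, ZC,
SSC, WL, MAV, MAVS, WAMP, AR(5) coefficients, MNF, PSR) concatenated
with the transposed 18×6 ACC map (MEAN, VAR, RMS, WL, MAV, MAVS per
channel). The classifier applies, in order:

- **Envelope input attention** — each standardized row z is weighted
  by its normalized Hilbert amplitude envelope,
  `z ⊙ A(z)/mean(A(z))`, with `A(z) = |z + i·H[z]|`, amplifying local
  waveform bursts while leaving stationary rows ≈ unchanged;
- **8 × conv1d** (100 filters, kernel 2, stride 1, no pooling), the
  first seven followed by **SENet channel gates**
  `s = σ(W₂·relu(W₁·x_sq))` on the global-average-pooled channels;
- **simAM neuron attention** after the last convolution: every neuron
  q gets weight `σ(1/e*)` from the closed-form minimum energy
  `e*(q) = 4(σ̂²+λ) / ((q−μ̂)² + 2σ̂² + 2λ)` (pooled channel statistics,
  λ = 10⁻⁴, zero trainable parameters);
- dense(16, ReLU) → dense(3, softmax).

Training is Adam on categorical cross-entropy with early stopping;
evaluation is stratified 10-fold cross-validation (accuracy,
precision, recall, F1, one-vs-rest per class and support-weighted),
plus a pseudo-artifact robustness protocol that re-runs the whole
pipeline with cross-modal contamination at weights 0.1/0.2/0.5 in
both directions. Because matched human recordings are rarely
shareable, the package ships a seeded synthetic generator whose
classes follow fatigue physiology: sEMG mean power frequency falls
(120/95/70 Hz) and amplitude rises (gains 1.0/1.3/1.7) with fatigue,
and accelerometer variability rises around a fixed 1.2 Hz cadence.
See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
from fatiguefuse import (SynthConfig, generate_dataset,
                         fused_maps_from_dataset, ModelConfig,
                         FatigueCNN, cross_validate)

data = generate_dataset(SynthConfig(epochs_per_class=30, seed=1))
X, y = fused_maps_from_dataset(data)        # X: (90, 6, 60)

model = FatigueCNN(ModelConfig(max_epochs=10, patience=0,
                               val_fraction=0.0, seed=1), "full")
res = model.fit(X, y)
print(res.summary())

cv = cross_validate(X, y, model.config, k=5, ablation="full", seed=1)
print(cv.summary())
```

prints

```
FatigueCNN fit results
======================================================
ablation:            full
trainable params:    246467
param breakdown:     {'conv': 142000, 'senet': 8400, 'simam': 0, 'dense': 96067, 'lfam': 0}
training examples:   90
epochs run:          10
final train loss:    0.0000
final train acc:     1.0000
5-fold cross-validation (seed 1)
accuracy:    0.9889 +/- 0.0248
weighted F1: 0.9888
```

The parameter breakdown is the attention audit: the seven SENet gates
carry 8400 trainable weights (1200 each at reduction 16 over 100
filters), while the envelope and simAM stages add none. Near-perfect
cross-validated accuracy reflects the deliberate separability of the
synthetic classes, not expected performance on human data.

The same pipeline is scriptable from the shell:

```sh
fatiguefuse simulate   --config run.yaml --out raw/
fatiguefuse preprocess --in raw/ --out epochs/
fatiguefuse features   --epochs epochs/ --out feat/
fatiguefuse train      --features feat/ --config run.yaml --ablation full --out model/
fatiguefuse evaluate   --model model/ --features feat/ --report report.tsv
fatiguefuse robustness --config run.yaml --out robustness/
```

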