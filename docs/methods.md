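# Methods

## Problem and pipeline

The task is binary classification: given a point-of-care FTIR absorbance
spectrum of a street-drug sample, predict the result of a fentanyl
immunoassay strip run on the same sample. Strips detect fentanyl and a wide
range of analogues down to very low weight fractions, so they serve as the
reference label; visual FTIR interpretation by a technician can only detect
fentanyl above roughly 3–10 % by weight, which is the gap the classifier is
meant to close.

The pipeline is: JCAMP-DX parsing → validation → cubic-spline resampling →
standardization → six-layer 1D conv net → thresholded prediction →
bootstrap diagnostics.

## Preprocessing

A spectrum is accepted iff it has at least 1,626 sampling points and its
wavenumbers cover [600, 3,800] cm⁻¹ including both endpoints. The point
threshold is treated as a pure configurable cutoff. Accepted spectra are
interpolated with a cubic spline through *all* points (no truncation of
points outside the required range) and evaluated at 600, 602, …, 3,798 cm⁻¹,
giving exactly 1,600 features; the vector is then standardized per spectrum
to zero mean and unit standard deviation.

Numerical choices, pinned for determinism:

- **Spline boundary condition: natural** (second derivative zero at the end
  knots). Because the grid endpoints (600 and 3,798 cm⁻¹) lie inside the
  required data range, the boundary choice has negligible effect; a single
  pinned convention keeps results exactly reproducible.
- **Population (divide-by-N) standard deviation** in standardization.
- Duplicate wavenumbers on read keep the first occurrence and log a warning.
- A constant (zero-variance) spectrum is a degenerate-spectrum error, not a
  silently-zero feature vector.

## The classifier

Layer order and sizes are fixed: input 1,600 → conv (8 filters, kernel 12,
ReLU) → dropout 0.5 → max-pool 2 → dense 32 (ReLU) → dense 1 (sigmoid).
The printed layer lengths force two interpretations that we adopt:
valid (no-padding) convolution (1,589 = 1,600 − 12 + 1) and pooling that
drops the final unpaired element (794 = ⌊1,589/2⌋). Two further choices the
architecture description leaves open:

- The 8 pooled feature maps are **flattened** (794 × 8 = 6,352 inputs) before
  the 32-unit dense layer, rather than globally pooled.
- Dropout sits between the convolution and the pool, following the stated
  layer order even though dropout-before-pool is unconventional.

Training: Adam (learning rate 10⁻³), binary cross-entropy, batch size 32,
50 epochs, stratified 80/20 train/test split. These four values are not
fixed by the problem statement; they are common defaults and are exposed in
`TrainConfig`. After each epoch, accuracy at the 0.5 threshold is measured
on the test split and the checkpoint with the highest test accuracy is kept
(earliest epoch on ties). Selecting the checkpoint on the same split used
for reporting leaks information and mildly biases the reported accuracy
upward; it is kept because it is the procedure being reproduced.
Classification is closed at the threshold: a score of exactly 0.5 is a
positive call.

The network is implemented directly in NumPy (im2col convolution via BLAS
matmuls, inverted dropout, argmax-routed pooling gradients). Training runs
in float32 for speed; stored weights are float64. All randomness — weight
initialization (Glorot uniform), the split shuffle, batch order, dropout
masks — derives from one user seed via `numpy.random.SeedSequence`, so
training is bit-reproducible on a single thread.

## Evaluation

Point estimates come from the 2×2 confusion table with strip-positive as the
positive class: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean, accuracy = (TP+TN)/N. Zero-denominator ratios are reported as
*undefined*, never coerced to 0. AUROC is computed on the continuous scores
with the rank (Mann–Whitney) formulation, ties half-credited — equivalent to
trapezoidal integration of the ROC curve.

Confidence intervals are **percentile bootstrap** (2.5th/97.5th quantiles of
the metric over 10,000 resamples of (prediction, label) pairs). The model is
not refit per resample — the CIs describe sampling variability of the
evaluation set under fixed predictions. Resamples on which a metric is
undefined (e.g. no predicted positives) are redrawn and counted; more than
50 % undefined aborts with an error. BCa intervals were not used; the
percentile method is the simplest defensible convention and is pinned.

The low-concentration secondary analysis selects samples with
truth = 1, model = 1, comparator = 0 and reports the count and the
median/Q1/Q3 of fentanyl concentration (percent by weight), using
linear-interpolation quantiles.

## The simulator

Synthetic samples emulate the cohort structure of a drug-checking service:

- **Spectra**: Beer–Lambert additivity. Absorbance(ν) = Σ_c w_c·A_c(ν) +
  baseline(ν) + ε(ν). Pure-component spectra A_c are sums of 4–10
  Gaussian/Lorentzian peaks from a fixed shipped library (fentanyl plus six
  cuts/actives: caffeine, heroin, methamphetamine, mannitol, inositol,
  lactose). Fentanyl has two bands ≥ 30 cm⁻¹ from every other component's
  band centers, so its fingerprint is identifiable; pairwise cosine
  similarity between pure spectra is below 0.95. Peak positions are
  invented — the simulator targets the statistical structure of the
  classification problem, not spectroscopic accuracy.
- **Cohort**: exactly ⌊0.481·n + 0.5⌋ positives (deterministic count so
  class-balance tests are exact). Positives draw fentanyl weight fraction
  log-uniformly on [0.2 %, 15 %]; the remaining weight splits over 1–3
  randomly chosen cuts via a Dirichlet draw. Negatives contain cuts only.
  The log-uniform law is a modelling choice: the real concentration
  distribution of all positives is unknown, and this law puts a substantial
  share (~74 %) of positives below the FTIR-limit analogue, matching the
  qualitative finding that technician-missed positives cluster at low
  concentrations.
- **Labels**: strip_label = 1 iff fraction ≥ 0.05 % (strip LOD analogue);
  ftir_proxy_label = 1 iff fraction ≥ 5 % (FTIR visual-read LOD analogue,
  middle of the 3–10 % range). By construction every positive below 5 % is
  proxy-negative, so the proxy's recall on that stratum is exactly 0 — the
  failure mode the network is supposed to beat.
- **Noise and drift**: Gaussian noise with SD 0.001 absorbance units
  (typical RMS noise of a benchtop ATR-FTIR) and a degree-2 polynomial
  baseline with coefficients drawn so |baseline| stays below 20 % of the
  maximum pure-component signal, exercising standardization robustness.
- Generation is a pure function of (config, library): same seed, same bytes.

What passing tests on simulated data do **not** show: performance on real
spectra. Real FTIR data have instrument response functions, ATR penetration
effects, water/CO₂ bands, scattering baselines and far richer mixtures; the
simulator has none of these. Test results demonstrate that the pipeline's
arithmetic, training loop and diagnostics behave as specified, and that the
network can learn sub-LOD detection when the signal is present — not that a
given accuracy transfers to field data.

## Problem sizes

End-to-end checks simulate n = 2,000 samples and train for 50 epochs; the
accuracy bar (median best test accuracy ≥ 0.9 over five seeds) and the
low-concentration recall comparison are evaluated at this scale, which a
single CPU core handles in about a minute per run. Bootstrap CIs always use
the full 10,000 resamples.

## Known limitations

- Test-split checkpoint selection (above) slightly biases reported accuracy.
- The JCAMP-DX reader covers XYPOINTS and AFFN (X++(Y..Y)) tables only;
  SQZ/DIF/DUP-compressed ordinates and multi-block files are rejected with
  a clear error. Transmittance spectra are rejected rather than converted.
- The simulator's FTIR-proxy label is a deterministic threshold on the true
  concentration; a real technician's calls are noisier.
- Single-threaded determinism is guaranteed; NumPy built against a
  different BLAS may produce bit-different (though statistically identical)
  training runs.
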