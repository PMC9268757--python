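# Methods

## Signal model and preprocessing

A trial is a channels × samples float64 matrix at sampling rate fs with a
prompt label (11 classes, phonemes before words in the fixed integer
encoding) and a protocol stage; only the imagined-speech stage is decoded.
Preprocessing applies, in order:

1. **Power-line notch.** One second-order IIR notch per multiple of the
   mains frequency strictly below Nyquist (for fs = 1000 Hz and 60 Hz mains:
   60…480 Hz), quality factor Q = 30, applied forward-backward so the
   cascade is zero-phase. Q = 30 is this package's choice — narrow enough
   (−3 dB width f₀/30) to leave neighbouring EEG rhythms within 1 dB while
   attenuating the tone itself by ≥ 30 dB in steady state. `filtfilt` uses
   reflect padding of about one second so the start-up transient stays out
   of the retained samples.
2. **Transition trim.** The first and last 0.5 s of each trial are dropped
   (imagery onset/offset transitions); a 5 s trial becomes 4 s.
3. **Windowing.** Non-overlapping windows of 0.25/0.5/1 s (any length with
   integral win_len × fs is accepted) cut from sample 0; a trailing
   remainder is discarded, never zero-padded, so W is constant.
4. **Split.** Within each recording independently, a uniformly random half
   of its windows goes to the training set and half to the test set
   (seeded; the extra window of an odd count goes to train). This
   window-level protocol lets windows of one trial appear on both sides —
   within-trial leakage that inflates absolute accuracies. It is kept
   because it is the reference protocol; `split_by_recording` provides the
   leakage-free alternative for those who want trial-level generalization.

## Features

`ccv_time` builds the C × C matrix of zero-lag cross-covariances of the raw
window samples; `ccv_frequency` first takes the unnormalized DFT of each
channel (length n = W, one-sided magnitudes including DC and, for even n,
Nyquist), optionally smooths the magnitude bins with a centered 3- or 5-bin
moving average (B3/B5; edges replicate the boundary bin, so constant
spectra are fixed points), then takes cross-covariances across frequency
bins. Both use the population 1/W normalization, not 1/(W−1). Covariance on
**magnitude** spectra is a deliberate choice (complex covariance or power
spectra were alternatives): magnitudes make the bin-smoothing variants
well-defined and give the delay-elimination property its exact form —
per-channel circular time shifts change nothing in a magnitude spectrum, so
frequency-domain features are invariant to them (≤ 1e-9 relative in tests)
while time-domain features are not.

Both matrix types are sample covariance Gram matrices, hence symmetric
positive semidefinite — asserted as a standing invariant. Before
classification each matrix is independently z-scored over its entries
(default on; a zero-spread matrix maps to zero). Raw covariances vary by
orders of magnitude across windows, and the network's activations expect
O(1) inputs; per-matrix standardization is an addition of this package, not
part of the reference protocol.

## Classifier

Architectures are parsed from `C<f1>-<f2>…/D<d1>…` strings into: a stack of
2-D convolutions (3 × 3 kernels, stride 1, no padding, no pooling — the
reference text names only filter counts, and 62 × 62 inputs shrink
gracefully under valid convolutions; kernel size is a config knob), a
flatten, hidden dense layers with tanh, and a fixed 11-unit softmax output.
Conv activation (tanh vs relu) is an experiment axis. The engine is pure
NumPy/BLAS: im2col convolutions (column blocks copied per kernel position so
every GEMM is large and contiguous), float32 parameters with Glorot-uniform
seeded initialization, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with in-place
updates, categorical cross-entropy, and optional early stopping
(patience 10 on validation loss, best weights restored). Backprop is
verified against central finite differences in the test suite. Exact ties
in the output argmax resolve to the lower class index.

Training protocol: the train split is partitioned into k = 4 class-stratified
folds (so each fold's validation share is 25%, matching the 75/25
prescription); each fold trains a fresh seeded network on the other folds
and is scored on the fixed test split. The ± spread reported with every
metric is the population standard deviation over folds. Defaults:
learning rate 1e-4, batch 32, up to 50 epochs. Whether accuracies are
window-level or trial-level (majority vote) was an open choice;
window-level is implemented.

`estimate_complexity` counts k²·N²·nF^(l−1)·nF^l multiplies per conv layer
with nF⁰ = 1 and N fixed at the input side for every layer (the inputs are
square and valid 3 × 3 convolutions shrink them only slightly), and
fan_in × fan_out per dense layer, with fan_in of the first dense taken from
the true flattened geometry; parameters are 4 bytes each (float32).

## Metrics

Computed from each fold's confusion matrix on the test split, then averaged:
accuracy (trace/total), balanced accuracy (mean per-class recall; classes
with zero support are excluded with a logged warning), macro recall
(definitionally identical to balanced accuracy, kept as its own named
metric to mirror standard reporting), and Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e from the row/column marginals. Confusion
matrices are averaged entrywise over folds. Metrics are fold-averaged, not
pooled, to match the mean-of-k-folds presentation. The grid runner sweeps
domain × window × smoothing × activation × architecture, reuses one
windowing/split per window length so feature comparisons see identical
window assignments, derives each cell's training seed from the cell key
(results independent of iteration order), and records per-cell failures
without aborting the sweep.

## Synthetic data

The generator emulates the statistical skeleton the features presume, not
EEG biophysics. Per class: a mixing matrix (n_channels × n_sources, i.i.d.
normal scaled by `mixing_scale`) and a list of passbands. Per trial:
sources are unit-variance Gaussian noise ideally band-limited by zero-phase
FFT masking, mixed into channels, plus white sensor noise
(`noise_sigma`). With `delay_jitter` on, each channel is independently
**circularly** delayed by a seeded lag ≤ `max_delay` — circular rather than
linear shifts so the frequency-feature invariance is exact, making the
time-vs-frequency comparison a controlled property instead of an empirical
accident. Class structure is carried by both mixing and bands so both
feature domains are informative until jitter selectively degrades the time
domain.

Defaults mirror one subject's inventory: 11 classes × 12 trials of 5 s
(pre-trim) at 62 channels, 4 sources, mixing_scale 1, noise_sigma 1 (≈ 6 dB
SNR against the mixed-source amplitude), jitter off, fs = 1000 Hz — chosen
so the standard window lengths have integral sample counts; the reference
database's rate is not public knowledge here, so fs is always read from
file/manifest, never assumed. Default bands tile 2 Hz–0.45·fs with two
disjoint slots per class. Everything is a pure function of the spec's seed.

What passing tests on this generator do **not** show: robustness to 1/f
background, ocular/muscle artifacts, volume-conduction correlations between
noise channels, non-stationarity across a session, or inter-subject
variability. Absolute accuracies here (≈ 1.0 on the separable defaults) say
the pipeline recovers planted covariance structure, not that real imagined
speech is decodable at that level.

## Problem sizes and numerical choices

The end-to-end reference run (acceptance and test suite) uses the default
132-trial dataset, 0.25 s windows (2112 windows, 50/50 split),
frequency-B0 features, `C64-128/D64` with relu, k = 4, and 2 training
epochs — on this separable dataset held-out accuracy saturates within the
first epoch, so the budget is convergence-based, not tuned. The grid
comparison runs a reduced 6-class/16-channel jittered dataset with a
`C8/D16` network. Tolerances: feature oracles agree to 1e-12 (covariance)
and 1e-9 (DFT) relative; PSD eigenvalue floor −1e-8 × trace; symmetric
matmul output is explicitly symmetrized to kill last-bit asymmetry.
float32 forward passes bound the finite-difference gradient agreement at
~5e-2 relative. Degenerate inputs (empty labels, constant matrices,
too-short trials, kernels wider than spectra, folds exceeding class counts)
raise `ValueError` rather than being silently repaired.

## Limitations

No `.cnt` parsing (convert to EDF externally), no artifact removal or
re-referencing, no MFCC/statistical feature baselines, no channel
selection, no lagged cross-covariance sequences, no significance testing
between grid cells, and no transfer to unseen subjects — a new subject
requires retraining, as the protocol is subject-shared.
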