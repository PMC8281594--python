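# Methods

This note documents the models, algorithms and design choices behind
`afibnet`, in the order the pipeline runs them.

## Problem setting

Atrial fibrillation (AF) on a single-lead ECG is recognized by two
signatures: *irregularly irregular* R-R intervals, and the replacement
of the P-wave by low-amplitude fibrillatory (f) oscillations.  The
package implements a detector that learns these signatures directly
from fixed-length amplitude windows ("episodes") of 2700 samples, with
no resampling: recordings at any sampling frequency from 100 to 500 Hz
are segmented on their native grid, so one trained model serves
heterogeneous devices.  A 2700-sample window spans 5.4 s at 500 Hz and
27 s at 100 Hz — at any supported rate it contains at least the three
beats (two R-R intervals) an AF call requires.

## Synthetic ECG generator

The generator exists so that every downstream stage is testable
without downloading clinical databases.  It is deliberately a *rhythm*
simulator, not a cardiac electrophysiology model.

**Beat morphology.** Each beat is a sum of Gaussian bumps (Q, R, S, T,
and optionally P) placed at R-times; widths and amplitudes approximate
a lead-II complex with a 1 mV R-peak.  This is the usual
sum-of-Gaussians simplification of ECG synthesis; it forgoes the
dynamical-system coupling of heart-rate and morphology that ECGSYN-type
models provide.

**R-R interval model.**
* N (normal sinus): i.i.d. log-normal intervals with mean 60/HR and a
  small coefficient of variation (CV ≤ 0.05, default 0.03).
* AF: i.i.d. log-normal intervals with CV ≥ 0.15 (default 0.25) — a
  coarse but standard surrogate for "irregularly irregular" that avoids
  modeling atrioventricular-node dynamics.  The P-wave amplitude is
  forced to 0 and a 7 Hz sinusoid with a slowly drifting random phase
  (amplitude 0.10 mV) stands in for the fibrillatory baseline.
* Non-AF: three coarse variants — bradycardia (45 bpm), tachycardia
  (125 bpm), and ectopic beats (premature beats with compensatory
  pauses) — enough to exercise the three-class head without modeling
  each named arrhythmia.

Intervals are drawn in continuous time before discretization, so the
same seed produces the same beat times at any sampling frequency
(agreement within one sample of the coarser grid).  All randomness
flows from one counter-based (Philox) stream per record.

Per-record heart rates vary across a dataset (N: 60–90 bpm, AF:
85–110 bpm, reflecting AF's typically rapid ventricular response), so
the record population is not a single repeated waveform.

**Noise model.** Baseline wander (a <0.5 Hz sinusoid), 50 Hz powerline
interference, and white noise, each with configurable amplitude and
all zero by default.  The "realistic" preset (0.08 / 0.02 / 0.03 mV)
is a mild ambulatory mix chosen to exercise the denoiser, not a
calibrated noise model of any particular device.

**What passing tests on this data do and do not show.**  They show the
pipeline recovers the class-defining rhythm structure end-to-end under
controlled conditions.  They do not show clinical performance: real
ECG has morphology variation across leads and patients, non-stationary
noise, rhythm transitions within a record, and annotation ambiguity,
none of which the generator emulates.

## Denoising

An 8-level discrete wavelet transform with the Sym5 mother wavelet.
The two finest detail bands are soft-thresholded at the universal
threshold σ√(2 ln n), with σ estimated as the finest band's median
absolute deviation divided by 0.6745; the deepest approximation band
(baseline wander) is zeroed.  Which bands are touched is configurable
(`WaveletPlan`); with no thresholding and the approximation kept, the
transform reconstructs the input to floating-point accuracy.  Signals
too short for 8 levels get the deepest feasible decomposition with a
logged warning.  Denoising precedes segmentation and is applied to
whole records.

## Segmentation

Non-overlapping 2700-sample windows.  A trailing remainder of at least
half a window (1350 samples) is zero-padded at the tail to full
length; a shorter remainder is dropped; a record shorter than one
window yields exactly one padded episode.  Episode count is therefore
`max(1, floor(n/2700) + [n mod 2700 >= 1350])`.  Padded zeros are fed
to the network as-is (no masking).  Stride and the keep-threshold are
configuration, not constants baked into callers; overlap is off by
default.  Amplitudes are never normalized by default (the feature *is*
the mV amplitude along the window); a per-episode z-score option
exists but is off.

Episode quality control (≥3 detected R-peaks in the unpadded portion)
is reported but never used to drop data silently.

## R-peak detection

A Pan-Tompkins-style scheme: 3rd-order Butterworth band-pass 5–15 Hz
(zero-phase), peak-picking on the magnitude above 40% of its maximum
with a 0.2 s refractory period, then snapping each detection to the
local raw-signal maximum.  Deterministic; returns an empty set for
records under 1 s or with no activity.  This detector supports QC and
R-R statistics; the classifier itself never consumes its output.

## Network

The full classifier stacks 13 valid 1-D convolutions (kernel 3,
stride 1) in five blocks of (64, 64), (128, 128), (256×3), (512×3),
(512×3) filters, each block closed by a 2/2 max-pool, reducing 2700
input nodes to 78 per feature map.  The 78×512 = 39,936-wide flatten
feeds two 1000-unit dense layers and the class head — one sigmoid unit
for N-vs-AF (AF positive), three softmax units for N/AF/Non-AF.
Hidden activations are ReLU.  Every layer carries biases, giving
45,846,329 trainable parameters in the binary configuration; shape
tracing and parameter accounting are closed-form arithmetic over the
declarative config and are pinned row-for-row in tests.

The engine is a small numpy implementation (im2col convolution,
reverse-mode gradients verified against finite differences, Adam).
Weights are float32, initialized He-uniform (fan-in scaled) from a
seeded Philox stream, so a (config, seed) pair fully determines the
model.  Binary predictions threshold p(AF) at 0.5 with ties going to
AF; three-class predictions take the argmax (first maximum on ties).

### Scaled configuration

Training the 45.8M-parameter network is a GPU-scale job; for CPU-scale
experiments the package defines a reduced model with the same layer
vocabulary: conv16 → pool → conv32 → pool×3 → dense 512 → dense 64 →
head (≈2.8M parameters).  Two design points matter:

* *Aggressive pooling* (four pools, 168 positions at the flatten): the
  rhythm cues are position-independent, and a dense head can only read
  them out position-invariantly within a short optimization budget if
  the number of positions is small.  The pooling depth was chosen by
  measuring held-out per-episode error rates on large synthetic test
  sets; both shallower (more positions) and deeper (fewer) stacks
  classify worse under the 5-epoch budget.
* *A wide two-layer head*: with few gradient steps, total logit
  movement scales with head width; a direct linear readout or a narrow
  head under-converges badly at the default learning rate.

## Training protocol

k = 10 folds, ~90:10 train:validation, stratified by class.  Two
split modes: **inter-patient** (the unit of assignment is the subject;
no subject appears on both sides of any fold — the honest setting for
deployment claims) and **intra-patient** (episode-level, used for the
three-class case).  Class imbalance is handled by weighting the
cross-entropy with inverse-frequency weights n_total/(n_classes·n_c)
computed on each fold's training split — a closed-form stand-in for
weight tuning by resampling, chosen for reproducibility.

Optimization: Adam, learning rate 1e-4, batch 16, 100 epochs by
default (binary or categorical cross-entropy), no early stopping and
no schedule.  Epoch shuffling, fold assignment and initialization all
derive from the root seed; a rerun is byte-identical including the
persisted metric tables.

## Evaluation

Per-class one-vs-rest confusion counts and five metrics: accuracy,
sensitivity, specificity, precision, F1.  Zero-denominator ratios are
reported as NaN, never as 0.  Binary headline metrics are those of the
AF (positive) class with overall accuracy; three-class headlines are
macro-averages.  Fold averaging is the unweighted arithmetic mean.
Metrics are computed at episode level; record-level majority voting is
possible downstream but is not the reported quantity.

## Reference experiment sizes

The synthetic recovery experiment uses 500 episodes (250 per class,
one per record, 10 s at 250 Hz, 50 subjects), the scaled model, and
5 epochs under the full 10-fold inter-patient protocol, replicated
over 3 seeds — sized so the pipeline runs in minutes on one CPU.  The
reported quantity per replicate is the fold-averaged metric (the
protocol's headline number); a single 50-episode validation fold has
0.04 metric granularity, so per-fold values scatter while the 10-fold
average recovers sensitivity and specificity ≥ 0.95 with a clear
margin.

## Known limitations

* The generator's AF is stationary; paroxysmal AF (rhythm changes
  inside a record) is not simulated, so segmentation never has to
  split mixed-rhythm records.
* The WFDB support is a minimal format-16 subset (single .dat per
  record, MIT annotations with aux strings), sufficient for round-trip
  interoperability tests, not a full implementation.
* The f-wave surrogate is a narrow-band oscillation; real fibrillatory
  waves are broadband and amplitude-varying.
* Episode counts for hours-long records depend on the windowing stride;
  with the default non-overlapping stride the per-record episode count
  is length-determined and cannot be compared against pipelines that
  window with overlap.
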