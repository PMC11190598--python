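# Methods

This note documents the models, parameter choices and known limitations of
`emghht`. It complements the README's overview with the reasoning a
maintainer or reviewer needs.

## Pipeline model and assumptions

The pipeline assumes single-channel sEMG epochs at a fixed sampling rate
(500 Hz by default), each epoch containing one sustained gesture followed
by rest. Classification is epoch-level: no windowing, no streaming, no
multi-channel fusion. The trial-based split (trials 1–2 train, 3–6 test)
evaluates generalization across repetitions of the same gestures by the
same subjects, not across subjects.

## Surrogate sEMG generator

No public recording exists for the two gesture vocabularies, so the
generator produces amplitude-modulated band-limited Gaussian noise — the
standard stationary surrogate for interference-pattern surface EMG. Per
epoch: white Gaussian noise is confined to the class band by FFT-domain
masking (exactly band-limited, unlike an IIR approximation), scaled to the
class RMS, shaped by a trapezoidal activation envelope (10 % ramps; a Hann
option exists), and followed by a rest segment of low-amplitude noise
(relative SD 0.05 — rest is never silent in practice). The whole epoch then
receives optional powerline interference (50 Hz sinusoid at 5 % of the
class amplitude, random phase) and broadband measurement noise at a
configurable SNR (default 20 dB — a clean laboratory recording).

Per-epoch random streams derive from (seed, subject, class, trial), so a
dataset is bit-reproducible and any epoch can be regenerated in isolation.

### Default class parameters

The class defaults place gestures on a two-axis grid:

* **Spectral shape** — half the classes occupy a broad multi-octave band
  (10–70 Hz), the other half a narrow high band (75–115 Hz), with a 1 Hz
  per-level shift keeping every (centre, width) pair distinct. Broadband
  epochs split their energy across the first three IMFs; narrowband epochs
  concentrate in IMF1, because EMD adaptively tracks any sub-octave band as
  a single mode. The axis is therefore read out by the *distribution* of
  energy across IMFs.
* **Activation strength** — within each shape group, RMS amplitudes follow
  a ×1.5 ladder, read out by the *total* energy. Contraction intensity
  genuinely differs across grips by this order.

These are the two observables the M/STD/E/U feature set can resolve: for
fixed epoch length, M, STD and E are proportional (one energy per IMF), and
U adds an amplitude-distribution term. A purely centre-frequency code — the
first design tried — is invisible to these features, since EMD absorbs any
narrow band into IMF1 wherever it sits; the grid code is the honest
restatement of "classes are spectrally distinct" in terms the published
feature set can see. All bands stay below 125 Hz, where dominant surface
EMG energy lives; this also keeps the finest dyadic octave (125–250 Hz)
noise-dominated, the assumption behind the denoiser's noise-scale estimate.

### What the surrogate does not model

Motor-unit action potentials and recruitment dynamics, inter-subject
variability in band location (subjects differ only by noise realization),
electrode shift, movement artifact, and signal non-stationarity within the
active segment. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that spectrally/energetically distinct classes are
recovered; they do not predict accuracy on laboratory recordings.

## Denoising

Universal-threshold wavelet shrinkage: Daubechies-4, 4 levels, symmetric
extension, soft thresholding of detail coefficients at σ√(2 ln N) with
σ = MAD(finest details)/0.6745; the approximation band is never
thresholded; a zero threshold (noise-free input) leaves coefficients
untouched. All choices are configurable (`DenoiseConfig`).

Two caveats worth knowing. First, the MAD estimate assumes the finest
octave is noise-dominated; signals with genuine content above fs/4 inflate
σ and get over-thresholded. Second, shrinkage helps signals whose energy
concentrates in few coefficients — smooth/low-frequency content. A tone
inside a detail octave at 0 dB SNR has per-coefficient amplitude comparable
to the universal threshold itself, and *no* universal-style rule improves
it; the denoising benefit is measured on smooth-tone fixtures (5 Hz, inside
the level-4 approximation band), where the gain is ~12 dB at 0 dB input
SNR.

## Empirical Mode Decomposition

* **Extrema**: strict interior extrema; runs of equal samples count once at
  the run midpoint (floor on ties).
* **Envelopes**: cubic splines through the extrema with two extrema
  mirrored across each signal end — the standard way to control end swings
  without inventing data. With fewer than four support points the envelope
  degrades gracefully to linear interpolation.
* **Sifting termination**: the candidate is accepted when it already
  satisfies the IMF requirements (count condition and envelope mean below
  `mean_tol` = 0.05 of the envelope amplitude), or when the normalized
  change σ falls below δ = 0.025 — the midpoint of the conventional 2–3 %
  range — *and* the count condition holds. σ alone does not certify an IMF:
  on surrogate epochs, σ-only stopping left roughly half the modes in
  violation of the count condition, so the count requirement is part of the
  acceptance rule. `max_sift_iterations` = 500 is a termination safety
  bound only; the largest observed count to convergence is 110.
* **Depth**: `max_imfs` = 4. Deeper modes of 10 s epochs are erratic
  splits of the low-frequency residue; their near-zero training variance
  turns z-scored test features into extreme outliers that destroy
  classification. The first four modes cover the physiological band at
  500 Hz (≈ 15–250 Hz dyadically) and carry all class information.
* **Completeness** is structural: modes are subtracted from the running
  residue, so IMFs + residue telescope back to the input; the acceptance
  suite verifies ≤ 1e−8 of the input range over 100 epochs (measured:
  ~1e−16).
* **Hilbert step**: instantaneous amplitude is the analytic-signal modulus;
  instantaneous frequency is the unwrapped-phase gradient / 2π clipped to
  [0, fs/2]. Mean frequencies are amplitude²-weighted.

## Features

The four statistics are implemented exactly as published: M is the mean of
*squares* (not the arithmetic mean), STD is the uncentred unrooted
(1/(N−1))Σx², and U is read as −Σx² ln x² with 0·ln 0 := 0 — the closest
well-defined form of the printed expression. U is negative whenever sample
magnitudes exceed 1. Conventional counterparts (arithmetic mean, centred
sample SD, Shannon entropy of the normalized energy distribution) are
available via `convention="conventional"`; the published forms are the
default because fidelity wins over familiarity. Epochs yielding fewer than
`max_imfs` modes are zero-padded so the classifier input length is
constant.

## Classifier

Architecture input → 64 → 32 → k (the source describes a generic
multi-hidden-layer feedforward net without sizes; two hidden layers are
ample for a 16-dimensional input). Leaky-ReLU (slope 0.01) hidden units,
softmax output with max-subtraction for overflow safety, cross-entropy
loss, plain mini-batch SGD (batch 16), seeded uniform init scaled by
1/√fan-in, float64 on one thread — bit-reproducible under a fixed seed.
Defaults lr = 0.05 for 400 epochs: at 0.01/200 plain SGD demonstrably
underfits protocol-sized training sets (training accuracy as low as 0.6);
the chosen defaults reach interpolation on every fixture while remaining
stable. Feature standardization (z-score fitted on the training split,
SD floored at 1e−12) is stored inside the parameters so prediction applies
it transparently. Ties in the argmax resolve to the lowest class index.

Degenerate cases are explicit errors: single-class training data,
dimension mismatches, and non-finite loss (which names the learning rate).

## Metrics

One-vs-rest reduction of the k×k confusion matrix; macro averages are
unweighted. A class absent from the evaluation set yields NaN for the
affected rate with a warning and is excluded from the macro average —
silent zeros would understate performance. Overall accuracy is
trace/total.

## Problem sizes

The acceptance script and test suite use: 100 surrogate epochs of 1 s
activity + 0.5 s rest for the decomposition properties; the full 5 s/5 s
protocol with 5 subjects (180 epochs) for the hand-grasp run and 3 subjects
(180 epochs) for the finger-movement run; 20 noise seeds for the denoising
gain; 1000-sample fixtures for tone oracles. These sizes make the whole
suite run in well under a minute while leaving every measured property far
from its tolerance.

## Known limitations

* Epoch-level, single-channel, offline only.
* EMD mode mixing is not mitigated (no ensemble/noise-assisted variants).
* The surrogate's class separability is designed in; real-data accuracy is
  out of scope by construction.
* The confusion tables published for the original recordings are
  internally inconsistent and are not reproduced; evaluation here is
  property-based.
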