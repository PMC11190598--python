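# emghht — sEMG hand-gesture classification with the Hilbert–Huang transform

`emghht` is a tested re-implementation of a myoelectric gesture-recognition
pipeline for single-channel surface electromyography (sEMG): raw epochs are
amplified and wavelet-denoised, decomposed by Empirical Mode Decomposition
(EMD) into intrinsic mode functions (IMFs), summarised by four statistics
per IMF, and classified by a small feedforward neural network. It is aimed
at researchers in biomedical signal processing and myoelectric control who
want an inspectable, seedable reference pipeline rather than a black box.

Two gesture vocabularies are built in: ten finger movements (`FM-10`:
H-C, T-L, T-R, T-M, T-I, T, L, R, M, I) and six hand grasps (`HG-6`: LG,
TG, CG, HG, SG, PG). Because no public recording accompanies these
vocabularies, the package ships a seeded surrogate generator that emulates
the acquisition protocol — 500 Hz sampling, 5 s active / 5 s rest epochs,
six repetitions per gesture, trials 1–2 for training and 3–6 for testing —
so every stage is testable end to end.

## The method

**Denoising.** The wavelet transform represents the physiological signal in
a few large coefficients while broadband noise spreads thinly, so soft
thresholding at the universal level σ√(2 ln N) (σ estimated as
MAD/0.6745 of the finest detail coefficients) removes noise with little
signal distortion.

**EMD / HHT.** Each IMF is extracted by *sifting*: with U_E and L_E the
cubic-spline envelopes through the local maxima and minima,

    μ(t) = (U_E(t) + L_E(t)) / 2,     h_i(t) = h_{i−1}(t) − μ{h_{i−1}}(t),

iterated until the normalized change σ_i = Σ|h_{i−1}−h_i|² / Σh_{i−1}²
falls below δ = 0.025 with the IMF count condition satisfied
(|#zero-crossings − #extrema| ≤ 1), and the mode is removed from the
running residue. The decomposition is complete by construction:
Σ IMFs + residue = input to machine precision. The Hilbert analytic signal
of each IMF yields instantaneous amplitude and frequency.

**Features.** Per IMF: mean power M = (1/N)Σx², spread STD = (1/(N−1))Σx²,
energy E = Σx², and log-energy entropy U = −Σx² ln x² (0·ln 0 := 0),
concatenated over the first four IMFs into a 16-dimensional vector.

**Classifier.** A dense network (input → 64 → 32 → classes) with leaky-ReLU
hidden units f(x) = x if x > 0 else 0.01x and a softmax output
p_j = e^{x_j}/Σ_k e^{x_k}, trained by mini-batch gradient descent on
cross-entropy with z-scored features.

**Evaluation.** Multi-class confusion matrices reduce one-vs-rest to
per-class TP/TN/FP/FN, giving Accuracy = (TP+TN)/(TP+TN+FP+FN),
Sensitivity = TP/(TP+FN) and Specificity = TN/(TN+FP), plus macro averages
and overall accuracy.

## Worked example

```python
from emghht import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(run_seed=1))
print(f"overall test accuracy : {report.overall_accuracy:.4f}")
```

prints

```
overall test accuracy : 0.9917
```

meaning that of the 180 surrogate hand-grasp epochs (6 grasps × 6 trials ×
5 subjects), the 120 held-out epochs from trials 3–6 are classified with
99.17 % accuracy by a network trained only on trials 1–2. The scripts in
`examples/` walk through each capability separately — simulation,
denoising, decomposition, feature extraction, and the full train/evaluate
run with per-class sensitivity and specificity.

A thin CLI mirrors the stages:

```bash
emghht simulate --vocabulary HG-6 --subjects 5 --out data.npz
emghht run-all --vocabulary HG-6 --seed 1 --out runs/hg6
```

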