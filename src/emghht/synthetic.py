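"""Seeded surrogate sEMG generator mirroring the acquisition protocol.

No public recording accompanies the gesture vocabularies, so every
downstream stage is exercised on surrogate data with the protocol's
structure: each epoch is 5 s of sustained activity followed by 5 s of rest,
each gesture is repeated over six trials, and each subject contributes one
epoch per gesture per trial.

The surrogate model for muscle activity is amplitude-modulated band-limited
Gaussian noise — the standard stationary approximation for interference-
pattern surface EMG.  Each gesture class is assigned its own spectral band
(centre/width in Hz) and activation amplitude, which is what makes the
classes separable and the end-to-end pipeline testable.  Optional powerline
interference (50/60 Hz sinusoid) and broadband measurement noise at a
configurable SNR corrupt the epochs so the denoising stage has real work to
do.  Rest segments are low-amplitude noise, not silence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .signal_io import VOCABULARIES, EMGSignal, GestureDataset


def _class_grid(n_classes: int) -> list[tuple[float, float, float]]:
    """(band low, band high, amplitude) per class on a shape-by-strength grid.

    Classes are coded along the two axes that real gestures vary on and that
    survive the decomposition: spectral *shape* (a broad multi-octave band,
    10-70 Hz, versus a narrow high band, 75-115 Hz — think slow postural
    contractions versus brisk phasic ones) and activation *strength* (RMS
    levels on a x1.5 ladder, since different grips recruit very different
    muscle mass).  The shape axis lands in the distribution of energy across
    the first modes of the decomposition; the strength axis lands in the
    total energy.  A 1 Hz per-level band shift keeps every (centre, width)
    pair distinct.  All bands stay below 125 Hz, where the dominant energy
    of surface EMG lives, which also leaves the finest dyadic octave
    (125-250 Hz at fs = 500) noise-dominated — the assumption behind the
    denoiser's robust noise-scale estimate.
    """
    levels = (n_classes + 1) // 2
    grid = []
    for c in range(n_classes):
        group, level = divmod(c, levels)
        if group == 0:
            lo, hi = 10.0 + level, 70.0 + level
        else:
            lo, hi = 75.0 + level, 115.0 + level
        grid.append((lo, hi, 1.5**level))
    return grid


def default_band_centers(n_classes: int) -> tuple[float, ...]:
    """Class band centres of the default shape-by-strength grid."""
    return tuple((lo + hi) / 2 for lo, hi, _ in _class_grid(n_classes))


def default_band_widths(n_classes: int) -> tuple[float, ...]:
    """Class full bandwidths of the default shape-by-strength grid."""
    return tuple(hi - lo for lo, hi, _ in _class_grid(n_classes))


def default_amplitudes(n_classes: int) -> tuple[float, ...]:
    """Per-class RMS activation levels (x1.5 ladder within each shape group)."""
    return tuple(amp for _, _, amp in _class_grid(n_classes))


@dataclass
class SynthesisConfig:
    """Parameters of the surrogate acquisition protocol.

    Defaults reproduce the protocol structure: 500 Hz sampling, 5 s active /
    5 s rest epochs, six repetitions, six hand-grasp classes, five subjects.
    """

    vocabulary: str = "HG-6"
    fs: float = 500.0
    active_duration: float = 5.0
    rest_duration: float = 5.0
    repetitions: int = 6
    n_subjects: int = 5
    class_band_centers: tuple[float, ...] | None = None
    class_band_widths: tuple[float, ...] | None = None
    class_amplitudes: tuple[float, ...] | None = None
    envelope_shape: str = "trapezoid"
    powerline_hz: float | None = 50.0
    powerline_amplitude: float = 0.05
    noise_snr_db: float = 20.0
    rest_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.vocabulary not in VOCABULARIES:
            raise ValidationError(
                f"unknown vocabulary {self.vocabulary!r}; registered: {', '.join(VOCABULARIES)}"
            )
        n = len(self.labels)
        if self.class_band_centers is None:
            self.class_band_centers = default_band_centers(n)
        if self.class_band_widths is None:
            self.class_band_widths = default_band_widths(n)
        if self.class_amplitudes is None:
            self.class_amplitudes = default_amplitudes(n)
        if not (len(self.class_band_centers) == len(self.class_band_widths) == n):
            raise ValidationError("need one band centre and width per class")
        if len(self.class_amplitudes) != n:
            raise ValidationError("need one amplitude per class")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.active_duration <= 0 or self.rest_duration < 0:
            raise ValidationError("durations must be positive (rest may be zero)")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        nyquist = self.fs / 2.0
        for c, w in zip(self.class_band_centers, self.class_band_widths):
            if c + w / 2.0 >= nyquist:
                raise ValidationError(
                    f"class band {c}±{w / 2} Hz exceeds the Nyquist limit {nyquist} Hz"
                )
        if self.powerline_hz is not None and self.powerline_hz >= nyquist:
            raise ValidationError("powerline frequency exceeds the Nyquist limit")
        if self.envelope_shape not in ("trapezoid", "hann"):
            raise ValidationError("envelope_shape must be 'trapezoid' or 'hann'")

    @property
    def labels(self) -> tuple[str, ...]:
        return VOCABULARIES[self.vocabulary]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [lo, hi] Hz via FFT masking."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:
        raise ValidationError(f"band [{lo}, {hi}] Hz contains no FFT bins at n={n}")
    return x / rms


def _activation_envelope(n: int, shape: str) -> np.ndarray:
    if shape == "hann":
        return np.hanning(n)
    ramp = max(int(round(0.1 * n)), 1)  # trapezoid: 10 % ramp up/down
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp)
    env[-ramp:] = np.linspace(1.0, 0.0, ramp)
    return env


def synthesize_epoch(
    config: SynthesisConfig, class_index: int, subject: int, trial: int
) -> EMGSignal:
    """One labelled epoch: modulated in-band activity followed by rest.

    The random stream is derived from (seed, subject, class, trial) so each
    epoch is independent yet the dataset is bit-reproducible.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject, class_index, trial])
    )
    fs = config.fs
    n_active = int(round(config.active_duration * fs))
    n_rest = int(round(config.rest_duration * fs))
    n = n_active + n_rest

    center = config.class_band_centers[class_index]
    width = config.class_band_widths[class_index]
    amp = config.class_amplitudes[class_index]

    active = _bandlimited_noise(rng, n_active, fs, center - width / 2, center + width / 2)
    active *= _activation_envelope(n_active, config.envelope_shape) * amp
    rest = config.rest_amplitude * rng.standard_normal(n_rest) if n_rest else np.empty(0)
    x = np.concatenate([active, rest])

    t = np.arange(n) / fs
    if config.powerline_hz is not None:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        x = x + config.powerline_amplitude * amp * np.sin(2 * math.pi * config.powerline_hz * t + phase)
    if math.isfinite(config.noise_snr_db):
        signal_power = np.mean(active**2)
        noise_power = signal_power / 10.0 ** (config.noise_snr_db / 10.0)
        x = x + math.sqrt(noise_power) * rng.standard_normal(n)

    return EMGSignal(
        samples=x,
        fs=fs,
        label=config.labels[class_index],
        subject_id=f"s{subject:02d}",
        trial_index=trial,
    )


def generate_dataset(config: SynthesisConfig) -> GestureDataset:
    """Full surrogate dataset: |vocabulary| x repetitions x n_subjects epochs."""
    epochs = [
        synthesize_epoch(config, c, s, r)
        for s in range(1, config.n_subjects + 1)
        for c in range(len(config.labels))
        for r in range(1, config.repetitions + 1)
    ]
    return GestureDataset(
        epochs=epochs,
        vocabulary=config.labels,
        vocabulary_name=config.vocabulary,
    )


def generate_tone_mixture(
    freqs,
    amps,
    fs: float = 500.0,
    duration: float = 1.0,
    seed: int | None = None,
    random_phase: bool = False,
) -> EMGSignal:
    """Sum of sinusoids — the standard fixture for decomposition oracles.

    Phases are zero unless ``random_phase`` is set, in which case they are
    drawn once from the seeded generator.  An empty frequency list yields the
    zero signal.
    """
    freqs = list(freqs)
    amps = list(amps)
    if len(freqs) != len(amps):
        raise ValidationError("freqs and amps must have equal length")
    for f in freqs:
        if not 0 <= f < fs / 2:
            raise ValidationError(f"tone at {f} Hz violates the Nyquist limit {fs / 2} Hz")
    n = int(round(duration * fs))
    if n < 2:
        raise ValidationError("duration too short for a 2-sample epoch")
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        phase = rng.uniform(0.0, 2.0 * math.pi) if random_phase else 0.0
        x += a * np.sin(2 * math.pi * f * t + phase)
    return EMGSignal(samples=x, fs=fs, label=None, subject_id="synthetic", trial_index=1)
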