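"""Amplification and wavelet-threshold denoising of raw epochs.

Surface EMG amplitudes sit in the tens-to-hundreds of microvolts and are
recorded through an analogue gain stage; :func:`amplify` models that stage
as an exact scalar gain.  Denoising exploits the sparsity of the wavelet
representation: the physiological signal concentrates in a few large
coefficients while broadband noise spreads thinly across all of them, so
shrinking small coefficients towards zero removes noise with little signal
distortion.

The threshold is the universal rule sigma * sqrt(2 ln N), with the noise
scale sigma estimated robustly from the median absolute deviation of the
finest-level detail coefficients (MAD / 0.6745).  Defaults — Daubechies-4,
four decomposition levels, soft thresholding, symmetric boundary extension —
are conventional for biomedical signals and fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ValidationError
from .signal_io import EMGSignal


@dataclass(frozen=True)
class DenoiseConfig:
    wavelet_name: str = "db4"
    decomposition_level: int = 4
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self):
        if self.decomposition_level < 1:
            raise ValidationError("decomposition_level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValidationError("threshold_mode must be 'soft' or 'hard'")


def amplify(signal: EMGSignal, gain: float) -> EMGSignal:
    """Scale an epoch by a positive gain, preserving all metadata."""
    if not gain > 0:
        raise ValidationError(f"gain must be positive, got {gain}")
    return signal.with_samples(signal.samples * gain)


def wavelet_denoise(signal: EMGSignal, config: DenoiseConfig = DenoiseConfig()) -> EMGSignal:
    """Wavelet shrinkage denoising; output has the input's length and metadata."""
    x = signal.samples
    n = x.size
    if n < 2**config.decomposition_level:
        raise ValidationError(
            f"epoch of {n} samples too short for decomposition level "
            f"{config.decomposition_level} (needs >= {2**config.decomposition_level})"
        )
    coeffs = pywt.wavedec(x, config.wavelet_name, level=config.decomposition_level, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    threshold = sigma * math.sqrt(2.0 * math.log(n))
    if threshold > 0:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode=config.threshold_mode) for c in coeffs[1:]
        ]
    else:  # noise-free signal: nothing to shrink
        denoised = coeffs
    y = pywt.waverec(denoised, config.wavelet_name, mode="symmetric")[:n]
    return signal.with_samples(y)
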