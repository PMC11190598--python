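"""Wavelet-threshold denoising of a noisy smooth signal.

A 5 Hz tone is buried in white noise at 0 dB SNR; universal-threshold soft
shrinkage on the Daubechies-4 coefficients recovers it.  The printed gain
is the improvement in SNR measured against the known clean tone.
"""

import numpy as np

from emghht import EMGSignal, wavelet_denoise

fs = 500.0
t = np.arange(1000) / fs
clean = np.sin(2 * np.pi * 5 * t)
rng = np.random.default_rng(0)
noise = rng.standard_normal(t.size) * np.sqrt(np.mean(clean**2))  # 0 dB SNR

noisy = EMGSignal(samples=clean + noise, fs=fs)
denoised = wavelet_denoise(noisy)

snr_in = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
snr_out = 10 * np.log10(np.mean(clean**2) / np.mean((denoised.samples - clean) ** 2))
print(f"input SNR  : {snr_in:6.2f} dB")
print(f"output SNR : {snr_out:6.2f} dB")
print(f"gain       : {snr_out - snr_in:6.2f} dB")
print()
print("The tone lives in the approximation band of the level-4 transform,")
print("so shrinking the detail coefficients removes noise, not signal.")
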