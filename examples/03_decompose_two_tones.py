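"""Empirical mode decomposition of a two-tone mixture.

EMD separates sin(2*pi*50 t) + sin(2*pi*5 t) into two intrinsic mode
functions without any basis choice: the fastest oscillation comes out
first.  The Hilbert step then reads off each mode's instantaneous
frequency.
"""

import numpy as np

from emghht import emd_decompose, generate_tone_mixture
from emghht.emd import mean_instantaneous_frequency

fs = 500.0
mixture = generate_tone_mixture([50.0, 5.0], [1.0, 1.0], fs=fs, duration=2.0)
imfset = emd_decompose(mixture)

print(f"extracted IMFs : {len(imfset)}")
recon_err = np.max(np.abs(imfset.reconstruction() - mixture.samples))
print(f"reconstruction : max |sum IMFs + residue - input| = {recon_err:.2e}")

t = np.arange(len(mixture)) / fs
for k, (imf, f_mean) in enumerate(zip(imfset.imfs, mean_instantaneous_frequency(imfset, fs)), 1):
    r50 = np.corrcoef(imf, np.sin(2 * np.pi * 50 * t))[0, 1]
    r5 = np.corrcoef(imf, np.sin(2 * np.pi * 5 * t))[0, 1]
    print(
        f"IMF{k}: mean instantaneous frequency {f_mean:5.1f} Hz,"
        f"  r(50 Hz tone) = {r50:+.3f},  r(5 Hz tone) = {r5:+.3f}"
    )
print()
print("IMF1 is the 50 Hz tone and IMF2 the 5 Hz tone (r close to 1); the")
print("decomposition sums back to the input to machine precision.")
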