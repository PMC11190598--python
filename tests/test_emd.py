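import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, sosfiltfilt

from emghht import (
    DegenerateSignalError,
    EmdConfig,
    EnvelopePair,
    ValidationError,
    compute_envelopes,
    emd_decompose,
    envelope_mean,
    find_extrema,
    hilbert_spectrum,
    sift,
)
from emghht.emd import mean_instantaneous_frequency, zero_crossings

from conftest import make_signal

FS = 500.0


def brute_force_extrema(x):
    """Naive neighbour scan — independent oracle for plateau-free signals."""
    maxima = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
    return maxima, minima


class TestFindExtrema:
    def test_monotone_ramp_has_no_interior_extrema(self):
        mx, mn = find_extrema(np.linspace(0, 1, 50))
        assert len(mx) == 0 and len(mn) == 0

    def test_constant_signal_has_no_extrema(self):
        mx, mn = find_extrema(np.ones(50))
        assert len(mx) == 0 and len(mn) == 0

    def test_two_hertz_sinusoid_counts(self):
        # peaks fall exactly between two equal samples (two-sample plateaus),
        # which the plateau-midpoint convention resolves to single extrema
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 2 * t)
        mx, mn = find_extrema(x)
        assert len(mx) == 2 and len(mn) == 2
        np.testing.assert_allclose(t[mx], [0.125, 0.625], atol=2 / FS)
        np.testing.assert_allclose(t[mn], [0.375, 0.875], atol=2 / FS)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_brute_force_on_noise(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        mx, mn = find_extrema(x)
        bmx, bmn = brute_force_extrema(x)
        assert list(mx) == bmx and list(mn) == bmn

    def test_plateau_counts_once_at_midpoint(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0, 0.0])
        mx, mn = find_extrema(x)
        assert list(mx) == [2]  # midpoint of samples 1..3
        assert list(mn) == [5]  # midpoint of samples 5..6 (floor)

    def test_needs_three_samples(self):
        with pytest.raises(ValidationError):
            find_extrema([1.0, 2.0])


class TestEnvelopes:
    def test_sinusoid_envelopes_are_flat_at_amplitude(self):
        # 10 Hz at 500 Hz: 50 samples/period, so sampled peaks sit within
        # 0.2 % of the true amplitude and the envelopes should be ~flat
        from emghht import generate_tone_mixture

        x = generate_tone_mixture([10.0], [1.0], fs=FS, duration=2.0).samples
        mx, mn = find_extrema(x)
        pair = compute_envelopes(x, mx, mn)
        interior = slice(50, -50)
        assert np.max(np.abs(pair.upper[interior] - 1.0)) <= 0.02
        assert np.max(np.abs(pair.lower[interior] + 1.0)) <= 0.02

    def test_envelope_interpolates_through_extrema(self, pure_tone):
        x = pure_tone.samples
        mx, mn = find_extrema(x)
        pair = compute_envelopes(x, mx, mn)
        np.testing.assert_allclose(pair.upper[mx], x[mx], atol=1e-9)
        np.testing.assert_allclose(pair.lower[mn], x[mn], atol=1e-9)

    def test_triangle_wave_envelopes_bracket_signal(self):
        from scipy.signal import sawtooth

        t = np.arange(1000) / FS
        x = sawtooth(2 * np.pi * 10 * t, width=0.5)
        mx, mn = find_extrema(x)
        pair = compute_envelopes(x, mx, mn)
        interior = slice(mx[0], mx[-1])
        assert np.all(pair.upper[interior] >= x[interior] - 1e-6)
        assert np.all(pair.lower[interior] <= x[interior] + 1e-6)

    def test_too_few_extrema_raises(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(DegenerateSignalError):
            compute_envelopes(x, np.array([], dtype=int), np.array([], dtype=int))


class TestEnvelopeMean:
    def test_symmetric_envelopes_have_zero_mean(self):
        pair = EnvelopePair(upper=np.full(10, 3.0), lower=np.full(10, -3.0))
        np.testing.assert_array_equal(envelope_mean(pair), 0.0)

    def test_constant_envelopes(self):
        pair = EnvelopePair(upper=np.full(10, 2.0), lower=np.zeros(10))
        np.testing.assert_array_equal(envelope_mean(pair), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            envelope_mean(EnvelopePair(upper=np.zeros(5), lower=np.zeros(6)))

    def test_dc_offset_recovered(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 25 * t) + 0.7
        mx, mn = find_extrema(x)
        mu = envelope_mean(compute_envelopes(x, mx, mn))
        assert np.median(np.abs(mu[100:-100] - 0.7)) <= 0.02


class TestSift:
    def test_pure_sinusoid_is_a_fixed_point(self, pure_tone):
        imf, state = sift(pure_tone.samples)
        assert state.iteration <= 3
        interior = slice(50, -50)
        rel = np.max(np.abs(imf[interior] - pure_tone.samples[interior]))
        assert rel <= 0.02

    def test_already_valid_imf_returned_unchanged(self, pure_tone):
        imf, state = sift(pure_tone.samples)
        assert state.iteration == 1
        np.testing.assert_array_equal(imf, pure_tone.samples)

    def test_terminates_within_iteration_cap(self, two_tone):
        cfg = EmdConfig(max_sift_iterations=5)
        _, state = sift(two_tone.samples, cfg)
        assert state.iteration <= 5
        assert np.isfinite(state.sigma) and state.sigma >= 0

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            sift(np.linspace(0, 1, 100))


class TestEmdDecompose:
    def test_reconstruction_identity(self, two_tone):
        imfset = emd_decompose(two_tone)
        err = np.max(np.abs(imfset.reconstruction() - two_tone.samples))
        assert err <= 1e-8 * np.ptp(two_tone.samples)

    def test_two_tone_imfs_match_bandpass_oracle(self, two_tone):
        """IMF1/IMF2 of 50+5 Hz reproduce band-filtered components at r >= 0.95."""
        imfset = emd_decompose(two_tone)
        assert len(imfset) >= 2
        sos_hi = butter(4, [30, 80], btype="bandpass", fs=FS, output="sos")
        sos_lo = butter(4, 15, btype="lowpass", fs=FS, output="sos")
        hi = sosfiltfilt(sos_hi, two_tone.samples)
        lo = sosfiltfilt(sos_lo, two_tone.samples)
        assert np.corrcoef(imfset.imfs[0], hi)[0, 1] >= 0.95
        assert np.corrcoef(imfset.imfs[1], lo)[0, 1] >= 0.95

    def test_constant_signal_decomposes_to_residue_only(self):
        sig = make_signal(np.full(100, 3.3))
        imfset = emd_decompose(sig)
        assert len(imfset) == 0
        np.testing.assert_array_equal(imfset.residue, sig.samples)

    def test_imf_validity_zero_crossings_vs_extrema(self, two_tone):
        imfset = emd_decompose(two_tone)
        for imf in imfset.imfs:
            mx, mn = find_extrema(imf)
            assert abs(zero_crossings(imf) - (len(mx) + len(mn))) <= 1

    def test_mean_frequency_strictly_decreasing(self):
        from emghht import generate_tone_mixture

        sig = generate_tone_mixture([80.0, 20.0, 5.0], [1.0, 1.0, 1.0], fs=FS, duration=2.0)
        imfset = emd_decompose(sig, EmdConfig(max_imfs=3))  # one mode per tone
        freqs = mean_instantaneous_frequency(imfset, FS)
        assert len(freqs) == 3
        assert all(a > b for a, b in zip(freqs, freqs[1:]))

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            emd_decompose(make_signal([1.0, 2.0, 1.0, 2.0]))


class TestHilbertSpectrum:
    def test_tone_instantaneous_frequency(self, pure_tone):
        imfset = emd_decompose(pure_tone)
        amp, freq = hilbert_spectrum(imfset, FS)[0]
        assert abs(np.median(freq) - 50.0) <= 1.0

    def test_tone_instantaneous_amplitude(self):
        from emghht import generate_tone_mixture

        sig = generate_tone_mixture([50.0], [2.5], fs=FS, duration=2.0)
        imfset = emd_decompose(sig)
        amp, _ = hilbert_spectrum(imfset, FS)[0]
        interior = slice(100, -100)
        np.testing.assert_allclose(amp[interior], 2.5, rtol=0.05)

    def test_zero_imf_gives_zero_amplitude(self):
        from emghht.emd import IMFSet

        imfset = IMFSet(imfs=[np.zeros(64)], residue=np.zeros(64), sift_counts=[1], source_length=64)
        amp, freq = hilbert_spectrum(imfset, FS)[0]
        np.testing.assert_array_equal(amp, 0.0)

    def test_empty_imfset_rejected(self):
        from emghht.emd import IMFSet

        empty = IMFSet(imfs=[], residue=np.zeros(64), sift_counts=[], source_length=64)
        with pytest.raises(ValidationError):
            hilbert_spectrum(empty, FS)
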