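"""Empirical Mode Decomposition and the Hilbert spectral step.

EMD adaptively decomposes a signal into a small ordered set of intrinsic
mode functions (IMFs) plus a residue.  An IMF is an oscillation whose
zero-crossing and extrema counts differ by at most one and whose local
envelope mean is near zero.  Each IMF is extracted by *sifting*: the mean of
the cubic-spline upper and lower envelopes (through the local maxima and
minima respectively) is subtracted from the current candidate,

    h_i(t) = h_{i-1}(t) - mu{h_{i-1}}(t),   mu = (U_E + L_E) / 2,

until either the normalized squared change between consecutive candidates

    sigma_i = sum_t |h_{i-1}(t) - h_i(t)|^2 / sum_t h_{i-1}(t)^2

drops below the threshold delta (default 0.025, the midpoint of the usual
2-3 % range), or the candidate already satisfies both IMF halting
requirements (zero-crossing/extrema counts within one of each other, and an
envelope mean that is small relative to the envelope amplitude).  The IMF is
subtracted from the running residue and sifting repeats on what remains,
stopping when the residue is monotone/degenerate or the requested number of
IMFs is reached.  By construction the IMFs and residue sum back to the input
exactly (telescoping), and successive IMFs carry decreasing mean frequency:
the first holds the broadest, fastest band.

Boundary treatment: envelopes are splined through extrema mirrored (two per
side) across the signal ends, which controls end swings without inventing
data.  Plateaus of equal samples count as a single extremum at their
midpoint.

The Hilbert step completes the Hilbert-Huang transform: each IMF's analytic
signal yields an instantaneous amplitude (its modulus) and an instantaneous
frequency (the unwrapped-phase derivative over two pi, clipped to the
physical band [0, fs/2]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as _analytic

from .errors import DegenerateSignalError, ValidationError
from .signal_io import EMGSignal


@dataclass(frozen=True)
class EmdConfig:
    """Sifting controls.

    delta is the sifting-termination threshold on sigma; mean_tol bounds the
    envelope mean (relative to the envelope amplitude) in the IMF validity
    check; max_imfs caps the decomposition depth, keeping the number of
    modes modest and constant across epochs so feature vectors have a fixed
    length.
    """

    delta: float = 0.025
    max_imfs: int = 4
    max_sift_iterations: int = 500  # safety bound only; sifting normally converges far earlier
    mean_tol: float = 0.05
    spline: str = "cubic"
    boundary: str = "mirror"

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValidationError("delta must lie in (0, 1)")
        if self.max_imfs < 1:
            raise ValidationError("max_imfs must be >= 1")
        if self.max_sift_iterations < 1:
            raise ValidationError("max_sift_iterations must be >= 1")
        if self.spline != "cubic" or self.boundary != "mirror":
            raise ValidationError("only cubic splines with mirror boundaries are supported")


@dataclass(frozen=True)
class EnvelopePair:
    upper: np.ndarray
    lower: np.ndarray


@dataclass(frozen=True)
class SiftState:
    """Final state of one sifting run: candidate, residual and diagnostics."""

    h: np.ndarray
    r: np.ndarray
    sigma: float
    iteration: int
    stop_reason: str  # 'sigma' | 'validity' | 'max_iter' | 'degenerate'


@dataclass
class IMFSet:
    """Ordered IMFs plus residue; sums back to the source signal exactly."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int]
    source_length: int
    stop_reasons: list[str] = field(default_factory=list)
    final_sigmas: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruction(self) -> np.ndarray:
        """Sum of IMFs and residue — equals the decomposed signal."""
        total = self.residue.copy()
        for imf in self.imfs:
            total += imf
        return total


def find_extrema(samples) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima.

    Runs of equal samples (plateaus) count once, at the plateau midpoint.
    Monotone and constant inputs return empty arrays.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise ValidationError("need at least 3 samples to locate interior extrema")
    # compress plateaus: keep the first index of each run of equal values
    change = np.flatnonzero(np.diff(x) != 0.0)
    if change.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    starts = np.concatenate([[0], change + 1])  # run starts
    y = x[starts]
    d = np.sign(np.diff(y))
    turn = d[:-1] * d[1:] < 0  # sign change between consecutive slopes
    peak_runs = np.flatnonzero(turn) + 1  # index into the run sequence
    run_ends = np.concatenate([starts[1:] - 1, [x.size - 1]])
    mids = (starts[peak_runs] + run_ends[peak_runs]) // 2
    is_max = d[peak_runs - 1] > 0
    return mids[is_max], mids[~is_max]


def zero_crossings(samples) -> int:
    """Count sign changes, treating exact zeros as transparent."""
    s = np.sign(np.asarray(samples, dtype=np.float64))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to two extrema across each end of the signal."""
    left = [i for i in idx[:3] if i > 0][:2]
    right = [i for i in idx[-3:] if i < n - 1][-2:]
    ext_idx = np.concatenate(
        [[-i for i in reversed(left)], idx, [2 * (n - 1) - i for i in reversed(right)]]
    )
    lookup = {int(i): v for i, v in zip(idx, val)}
    ext_val = np.concatenate(
        [[lookup[i] for i in reversed(left)], val, [lookup[i] for i in reversed(right)]]
    )
    keep = np.concatenate([[True], np.diff(ext_idx) > 0])
    return ext_idx[keep], ext_val[keep]


def compute_envelopes(
    samples, maxima: np.ndarray, minima: np.ndarray, boundary: str = "mirror"
) -> EnvelopePair:
    """Cubic-spline envelopes through the extrema, mirror-extended at the ends."""
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    if boundary != "mirror":
        raise ValidationError("only mirror boundary extension is supported")
    if len(maxima) < 2 or len(minima) < 2:
        raise DegenerateSignalError(
            f"need >= 2 maxima and >= 2 minima for envelopes, got {len(maxima)}/{len(minima)}"
        )
    grid = np.arange(n)

    def _spline(idx: np.ndarray) -> np.ndarray:
        ei, ev = _mirror_extend(np.asarray(idx, dtype=int), x[np.asarray(idx, dtype=int)], n)
        if ei.size >= 4:
            return CubicSpline(ei, ev)(grid)
        return np.interp(grid, ei, ev)

    return EnvelopePair(upper=_spline(maxima), lower=_spline(minima))


def envelope_mean(pair: EnvelopePair) -> np.ndarray:
    """Pointwise mean of the upper and lower envelopes, mu = (U_E + L_E)/2."""
    if pair.upper.shape != pair.lower.shape:
        raise ValidationError("envelope length mismatch")
    return 0.5 * (pair.upper + pair.lower)


def _is_imf_candidate(h: np.ndarray, maxima, minima, mu: np.ndarray, pair: EnvelopePair, mean_tol: float) -> bool:
    counts_ok = abs(zero_crossings(h) - (len(maxima) + len(minima))) <= 1
    amp = np.max(np.abs(pair.upper - pair.lower)) / 2.0
    mean_ok = amp > 0 and np.max(np.abs(mu)) <= mean_tol * amp
    return counts_ok and mean_ok


def sift(samples, config: EmdConfig = EmdConfig()) -> tuple[np.ndarray, SiftState]:
    """Extract one IMF candidate by iterated envelope-mean subtraction.

    Stops at the first of: the candidate already satisfies the IMF halting
    requirements ('validity'); the normalized change sigma falls below delta
    while the zero-crossing/extrema count condition holds ('sigma' — a small
    sigma alone does not certify an IMF, so the count condition is required
    with it); the candidate loses the extrema needed for envelopes
    ('degenerate'); or the iteration cap is hit ('max_iter').  An input that
    is already an IMF is returned unchanged after a single check.
    """
    x = np.asarray(samples, dtype=np.float64)
    h = x.copy()
    sigma = 0.0
    maxima, minima = find_extrema(h)
    if len(maxima) < 2 or len(minima) < 2:
        raise DegenerateSignalError("input has too few extrema to sift")

    iteration = 0
    stop_reason = "max_iter"
    for iteration in range(1, config.max_sift_iterations + 1):
        pair = compute_envelopes(h, maxima, minima, config.boundary)
        mu = envelope_mean(pair)
        if _is_imf_candidate(h, maxima, minima, mu, pair, config.mean_tol):
            stop_reason = "validity"
            break
        h_new = h - mu
        denom = float(np.sum(h**2))
        sigma = float(np.sum(mu**2)) / denom if denom > 0 else 0.0
        h = h_new
        maxima, minima = find_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            stop_reason = "degenerate"
            break
        counts_ok = abs(zero_crossings(h) - (len(maxima) + len(minima))) <= 1
        if sigma < config.delta and counts_ok:
            stop_reason = "sigma"
            break

    return h, SiftState(h=h, r=x - h, sigma=sigma, iteration=iteration, stop_reason=stop_reason)


def _is_degenerate(r: np.ndarray) -> bool:
    if r.size < 3:
        return True
    maxima, minima = find_extrema(r)
    return len(maxima) < 2 or len(minima) < 2


def emd_decompose(signal: EMGSignal, config: EmdConfig = EmdConfig()) -> IMFSet:
    """Full decomposition: successive sifting on the running residue.

    A constant or monotone input yields zero IMFs with the input as residue.
    """
    x = np.asarray(signal.samples, dtype=np.float64)
    if x.size < 8:
        raise ValidationError("signal too short to decompose (need >= 8 samples)")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    reasons: list[str] = []
    sigmas: list[float] = []
    while len(imfs) < config.max_imfs and not _is_degenerate(residue):
        imf, state = sift(residue, config)
        if not np.any(imf):  # sifting produced nothing new
            break
        imfs.append(imf)
        counts.append(state.iteration)
        reasons.append(state.stop_reason)
        sigmas.append(state.sigma)
        residue = residue - imf
    return IMFSet(
        imfs=imfs,
        residue=residue,
        sift_counts=counts,
        source_length=x.size,
        stop_reasons=reasons,
        final_sigmas=sigmas,
    )


def hilbert_spectrum(imfset: IMFSet, fs: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-IMF instantaneous amplitude and frequency via the analytic signal.

    Frequency is the unwrapped-phase derivative / 2 pi, clipped to [0, fs/2].
    """
    if len(imfset) == 0:
        raise ValidationError("cannot compute a Hilbert spectrum of an empty IMF set")
    out = []
    for imf in imfset.imfs:
        analytic = _analytic(imf)
        amplitude = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic))
        frequency = np.clip(np.gradient(phase) * fs / (2.0 * np.pi), 0.0, fs / 2.0)
        out.append((amplitude, frequency))
    return out


def mean_instantaneous_frequency(imfset: IMFSet, fs: float) -> list[float]:
    """Amplitude-weighted mean instantaneous frequency per IMF (Hz)."""
    spectra = hilbert_spectrum(imfset, fs)
    means = []
    for amplitude, frequency in spectra:
        w = amplitude**2
        means.append(float(np.sum(w * frequency) / np.sum(w)) if np.sum(w) > 0 else 0.0)
    return means
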