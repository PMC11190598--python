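"""Per-IMF statistical features assembled into fixed-length classifier inputs.

Four scalar statistics summarise each intrinsic mode function:

    M   = (1/N)    * sum x_i^2        (mean power)
    STD = (1/(N-1))* sum x_i^2        (uncentered, unrooted spread)
    E   =            sum x_i^2        (energy)
    U   = - sum x_i^2 * ln(x_i^2)     (energy-weighted log entropy, 0*ln0 := 0)

These are the method's published forms, implemented literally; note that M
and STD are *not* the arithmetic mean and sample standard deviation their
names suggest, and U may be negative when samples exceed unit magnitude.
``convention="conventional"`` switches to the textbook counterparts
(arithmetic mean, centred sample SD, Shannon entropy of the normalized
energy distribution) for comparison studies.

Feature vectors are flattened per IMF in the order M, STD, E, U and
zero-padded up to ``4 * max_imfs`` entries so every epoch, however many
modes it decomposed into, feeds the classifier a vector of one fixed length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emd import IMFSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("M", "STD", "E", "U")


def _as_array(x, min_len: int, op: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.size < min_len:
        raise ValidationError(f"{op} needs at least {min_len} sample(s), got {arr.size}")
    return arr


def feat_mean_power(x) -> float:
    """Mean power M = (1/N) sum x_i^2."""
    arr = _as_array(x, 1, "feat_mean_power")
    return float(np.mean(arr**2))


def feat_std(x, convention: str = "as-printed") -> float:
    """Spread: (1/(N-1)) sum x_i^2 as printed, or the centred sample SD."""
    arr = _as_array(x, 2, "feat_std")
    if convention == "conventional":
        return float(np.std(arr, ddof=1))
    return float(np.sum(arr**2) / (arr.size - 1))


def feat_energy(x) -> float:
    """Energy E = sum x_i^2."""
    arr = _as_array(x, 1, "feat_energy")
    return float(np.sum(arr**2))


def feat_entropy(x, convention: str = "as-printed") -> float:
    """Log-energy entropy U = -sum x_i^2 ln(x_i^2), with 0*ln0 := 0.

    The conventional variant is the Shannon entropy of p_i = x_i^2 / E.
    """
    arr = _as_array(x, 1, "feat_entropy")
    sq = arr**2
    if convention == "conventional":
        total = np.sum(sq)
        if total == 0.0:
            return 0.0
        p = sq[sq > 0] / total
        return float(-np.sum(p * np.log(p)))
    nz = sq[sq > 0]
    return float(-np.sum(nz * np.log(nz)))


def feat_mean(x, convention: str = "as-printed") -> float:
    """'Mean' feature: mean power as printed, or the arithmetic mean."""
    if convention == "conventional":
        return float(np.mean(_as_array(x, 1, "feat_mean")))
    return feat_mean_power(x)


@dataclass(frozen=True)
class FeatureVector:
    """Flattened per-IMF features with the epoch's label and mode count."""

    values: np.ndarray
    label: str | None
    imf_count: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector contains non-finite values")


def extract_features(
    imfset: IMFSet,
    max_imfs: int,
    label: str | None = None,
    convention: str = "as-printed",
) -> FeatureVector:
    """M, STD, E, U of each of the first ``max_imfs`` IMFs, zero-padded."""
    if max_imfs < 1:
        raise ValidationError("max_imfs must be >= 1")
    if convention not in ("as-printed", "conventional"):
        raise ValidationError(f"unknown feature convention {convention!r}")
    values = np.zeros(4 * max_imfs)
    n_used = min(len(imfset), max_imfs)
    if len(imfset) == 0:
        logger.warning("empty IMF set: emitting an all-zero feature vector")
    for k in range(n_used):
        imf = imfset.imfs[k]
        values[4 * k : 4 * k + 4] = (
            feat_mean(imf, convention),
            feat_std(imf, convention),
            feat_energy(imf),
            feat_entropy(imf, convention),
        )
    return FeatureVector(values=values, label=label, imf_count=n_used)


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Feature matrix as a DataFrame: one row per epoch, label in the last column."""
    if not vectors:
        raise ValidationError("no feature vectors to tabulate")
    width = vectors[0].values.size
    if any(v.values.size != width for v in vectors):
        raise ValidationError("feature vectors have inconsistent lengths")
    n_imfs = width // 4
    columns = [f"imf{k + 1}_{name}" for k in range(n_imfs) for name in FEATURE_NAMES]
    frame = pd.DataFrame([v.values for v in vectors], columns=columns)
    frame["label"] = [v.label for v in vectors]
    return frame
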