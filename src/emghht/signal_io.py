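"""Labelled sEMG epochs, datasets, file round-tripping and the trial split.

An :class:`EMGSignal` is one single-channel epoch (a fixed-duration stretch of
surface-EMG samples) tagged with its gesture label, subject and trial index.
A :class:`GestureDataset` collects epochs sharing a sampling rate and a label
vocabulary, and carries the trial-based train/test assignment used throughout:
of the six repetitions of each gesture, two trials train the classifier and
four test it.

Two storage formats are supported: a human-readable CSV (one sample per row,
``time,amplitude,label,subject,trial``) and a binary ``.npz`` container with
one named array per epoch.  Both carry a JSON metadata sidecar
(``<path>.json``) holding the sampling rate, vocabulary and per-epoch
metadata; the sampling rate is always recovered from metadata, never inferred
from the CSV time column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: The two registered gesture vocabularies: ten finger movements and six
#: hand grasps (H-C = hand close; T-x = thumb paired with a finger;
#: T/L/R/M/I = single-digit flexions; LG..PG = lateral, tip, cylindrical,
#: hook, spherical and palmar grasps).
FM10 = ("H-C", "T-L", "T-R", "T-M", "T-I", "T", "L", "R", "M", "I")
HG6 = ("LG", "TG", "CG", "HG", "SG", "PG")
VOCABULARIES: dict[str, tuple[str, ...]] = {"FM-10": FM10, "HG-6": HG6}

_CSV_COLUMNS = ("time", "amplitude", "label", "subject", "trial")


@dataclass(frozen=True)
class EMGSignal:
    """One labelled single-channel sEMG epoch.

    Parameters
    ----------
    samples:
        Amplitude samples in microvolts.
    fs:
        Sampling rate in Hz (the acquisition protocol uses 500 Hz).
    label:
        Gesture identifier, or ``None`` for an unlabelled epoch.
    subject_id:
        Opaque subject identifier.
    trial_index:
        1-based repetition index within the protocol (1..6 by default).
    channel_id:
        Electrode channel name; the pipeline is single-channel.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    subject_id: str = "s01"
    trial_index: int = 1
    channel_id: str = "ch1"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("an epoch needs at least 2 samples in one channel")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("epoch contains non-finite samples")
        if self.trial_index < 1:
            raise ValidationError(f"trial_index must be >= 1, got {self.trial_index}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EMGSignal":
        """Copy of this epoch with new samples and identical metadata."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class GestureDataset:
    """A collection of epochs with a shared rate, vocabulary and trial split."""

    epochs: list[EMGSignal]
    vocabulary: tuple[str, ...]
    vocabulary_name: str | None = None
    split: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.vocabulary = tuple(self.vocabulary)
        if not self.split:
            # default protocol split: trials 1-2 train, the rest test
            self.split = {
                t: ("train" if t in (1, 2) else "test") for t in self.trial_indices()
            }
        self.validate()

    def validate(self) -> None:
        if self.epochs:
            fs0 = self.epochs[0].fs
            if any(e.fs != fs0 for e in self.epochs):
                raise ValidationError("all epochs in a dataset must share one sampling rate")
        vocab = set(self.vocabulary)
        for e in self.epochs:
            if e.label is not None and e.label not in vocab:
                raise ValidationError(f"label {e.label!r} not in vocabulary {self.vocabulary}")
        missing = self.trial_indices() - set(self.split)
        if missing:
            raise ValidationError(f"split does not cover trial indices {sorted(missing)}")
        bad = set(self.split.values()) - {"train", "test"}
        if bad:
            raise ValidationError(f"split values must be 'train'/'test', got {sorted(bad)}")

    def trial_indices(self) -> set[int]:
        return {e.trial_index for e in self.epochs}

    @property
    def fs(self) -> float:
        if not self.epochs:
            raise ValidationError("empty dataset has no sampling rate")
        return self.epochs[0].fs

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


def _infer_vocabulary(labels: Iterable[str]) -> tuple[str | None, tuple[str, ...]]:
    """Match a label set to exactly one registered vocabulary."""
    present = {l for l in labels if l is not None}
    hits = [(name, vocab) for name, vocab in VOCABULARIES.items() if present <= set(vocab)]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise ValidationError(
            f"labels {sorted(present)} match no registered vocabulary "
            f"({', '.join(VOCABULARIES)}); pass vocabulary= explicitly"
        )
    raise ValidationError(f"labels {sorted(present)} are ambiguous across vocabularies")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _epoch_meta(e: EMGSignal) -> dict:
    return {
        "label": e.label,
        "subject": e.subject_id,
        "trial": e.trial_index,
        "channel": e.channel_id,
        "n_samples": len(e),
    }


def write_epochs(dataset: GestureDataset, path, format: str = "csv") -> None:
    """Write a dataset to ``path`` in ``csv`` or ``npz`` format.

    A JSON sidecar ``<path>.json`` records the sampling rate, vocabulary,
    split and per-epoch metadata.  CSV uses a dot decimal separator and 17
    significant digits so a round trip preserves at least 12 digits.
    """
    path = Path(path)
    if not dataset.epochs:
        raise ValidationError("refusing to write an empty dataset")
    dataset.validate()
    meta = {
        "fs": dataset.fs,
        "vocabulary": list(dataset.vocabulary),
        "vocabulary_name": dataset.vocabulary_name,
        "split": {str(k): v for k, v in dataset.split.items()},
        "epochs": [_epoch_meta(e) for e in dataset.epochs],
    }
    if format == "csv":
        frames = []
        for e in dataset.epochs:
            n = len(e)
            frames.append(
                pd.DataFrame(
                    {
                        "time": np.arange(n) / e.fs,
                        "amplitude": e.samples,
                        "label": e.label if e.label is not None else "",
                        "subject": e.subject_id,
                        "trial": e.trial_index,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    elif format == "npz":
        arrays = {f"epoch_{i:05d}": e.samples for i, e in enumerate(dataset.epochs)}
        np.savez(path, **arrays)
        if path.suffix != ".npz":  # np.savez appends .npz when missing
            path = path.with_name(path.name + ".npz")
    else:
        raise ValidationError(f"unknown format {format!r} (expected 'csv' or 'npz')")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_epochs(path, format: str = "csv", fs: float | None = None) -> GestureDataset:
    """Read a dataset written by :func:`write_epochs`.

    ``fs`` is only consulted for CSV files lacking a metadata sidecar; the
    time column is never used to infer the rate.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    if format == "csv":
        epochs = _read_csv_epochs(path, meta, fs)
    elif format == "npz":
        if meta is None:
            raise ParseError(f"binary container {path} is missing its sidecar {sidecar}")
        with np.load(path) as archive:
            keys = sorted(k for k in archive.files if k.startswith("epoch_"))
            if len(keys) != len(meta["epochs"]):
                raise ParseError(f"{path}: {len(keys)} arrays but {len(meta['epochs'])} metadata entries")
            epochs = [
                EMGSignal(
                    samples=archive[k],
                    fs=meta["fs"],
                    label=m["label"],
                    subject_id=m["subject"],
                    trial_index=int(m["trial"]),
                    channel_id=m.get("channel", "ch1"),
                )
                for k, m in zip(keys, meta["epochs"])
            ]
    else:
        raise ValidationError(f"unknown format {format!r} (expected 'csv' or 'npz')")

    if meta is not None and meta.get("vocabulary"):
        name, vocab = meta.get("vocabulary_name"), tuple(meta["vocabulary"])
    else:
        name, vocab = _infer_vocabulary(e.label for e in epochs)
    split = (
        {int(k): v for k, v in meta["split"].items()}
        if meta is not None and meta.get("split")
        else {}
    )
    return GestureDataset(epochs=epochs, vocabulary=vocab, vocabulary_name=name, split=split)


def _read_csv_epochs(path: Path, meta: dict | None, fs: float | None) -> list[EMGSignal]:
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface pandas failure as ParseError
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if meta is not None:
        rate = float(meta["fs"])
    elif fs is not None:
        rate = float(fs)
    else:
        raise ParseError(f"{path}: no metadata sidecar; pass fs= explicitly")

    for col in ("amplitude", "trial"):
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & (table[col] != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: malformed {col!r} value on line {line}")
        table[col] = converted
    if table["trial"].isna().any():
        line = int(table["trial"].isna().idxmax()) + 2
        raise ParseError(f"{path}: empty 'trial' value on line {line}")

    # contiguous runs of (label, subject, trial) delimit epochs
    key = table["label"] + "\x00" + table["subject"] + "\x00" + table["trial"].astype(str)
    boundaries = (key != key.shift()).cumsum()
    epochs = []
    for _, group in table.groupby(boundaries, sort=False):
        label = group["label"].iloc[0]
        epochs.append(
            EMGSignal(
                samples=group["amplitude"].to_numpy(dtype=np.float64),
                fs=rate,
                label=label if label != "" else None,
                subject_id=group["subject"].iloc[0],
                trial_index=int(group["trial"].iloc[0]),
            )
        )
    return epochs


def split_by_trial(
    dataset: GestureDataset, train_trials: Sequence[int] | set[int] = (1, 2)
) -> tuple[GestureDataset, GestureDataset]:
    """Partition a dataset into train/test by trial index.

    The default assigns trials 1-2 to training and the remaining trials to
    testing, matching the acquisition protocol (six repetitions per gesture,
    two used for training and four for testing).
    """
    train_trials = set(train_trials)
    present = dataset.trial_indices()
    if not train_trials <= present:
        raise ValidationError(
            f"train_trials {sorted(train_trials)} not a subset of present trials {sorted(present)}"
        )
    train = [e for e in dataset.epochs if e.trial_index in train_trials]
    test = [e for e in dataset.epochs if e.trial_index not in train_trials]

    def _subset(epochs: list[EMGSignal], role: str) -> GestureDataset:
        return GestureDataset(
            epochs=epochs,
            vocabulary=dataset.vocabulary,
            vocabulary_name=dataset.vocabulary_name,
            split={t: role for t in {e.trial_index for e in epochs}} or {0: role},
        )

    return _subset(train, "train"), _subset(test, "test")
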