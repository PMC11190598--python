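"""End-to-end orchestration: simulate -> amplify -> denoise -> decompose ->
featurize -> split by trial -> train -> evaluate.

:func:`run_pipeline` executes the whole chain from one
:class:`PipelineConfig` and a single run seed, returning the evaluation
report for the held-out trials.  When an output directory is given, every
intermediate artifact (dataset, denoised epochs, IMF sets, feature matrix,
model, confusion matrix, report, resolved config) is written in a format
re-loadable by its module's reader, so a run is fully reconstructable from
the emitted config plus seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dnn, features, preprocessing, signal_io, synthetic
from .emd import EmdConfig, IMFSet, emd_decompose
from .metrics import ConfusionMatrix, MetricsReport, confusion_matrix
from .metrics import metrics as compute_metrics
from .errors import PipelineStageError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested stage configs plus the run seed and trial split."""

    synthesis: synthetic.SynthesisConfig = field(default_factory=synthetic.SynthesisConfig)
    denoise: preprocessing.DenoiseConfig = field(default_factory=preprocessing.DenoiseConfig)
    emd: EmdConfig = field(default_factory=EmdConfig)
    train: dnn.TrainConfig = field(default_factory=dnn.TrainConfig)
    train_trials: tuple[int, ...] = (1, 2)
    gain: float = 1.0
    feature_convention: str = "as-printed"
    run_seed: int = 0
    input_path: str | None = None  # load instead of simulate when set
    input_format: str = "npz"
    output_dir: str | None = None

    def resolved(self) -> "PipelineConfig":
        """Copy with the run seed propagated into every seeded stage."""
        return dataclasses.replace(
            self,
            synthesis=dataclasses.replace(self.synthesis, seed=self.run_seed),
            train=dataclasses.replace(self.train, seed=self.run_seed + 1),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with the stage name
                raise PipelineStageError(name, str(exc)) from exc

        return inner

    return wrap


def _epoch_id(e: signal_io.EMGSignal) -> str:
    return f"{e.subject_id}/{e.label}/trial{e.trial_index}"


@_stage("acquire")
def _acquire(config: PipelineConfig) -> signal_io.GestureDataset:
    if config.input_path is not None:
        logger.info("loading dataset from %s", config.input_path)
        return signal_io.read_epochs(config.input_path, format=config.input_format)
    logger.info(
        "simulating %s dataset: %d subjects x %d classes x %d trials",
        config.synthesis.vocabulary,
        config.synthesis.n_subjects,
        len(config.synthesis.labels),
        config.synthesis.repetitions,
    )
    return synthetic.generate_dataset(config.synthesis)


@_stage("preprocess")
def _preprocess(dataset: signal_io.GestureDataset, config: PipelineConfig) -> signal_io.GestureDataset:
    cleaned = []
    for e in dataset:
        logger.debug("preprocess %s", _epoch_id(e))
        cleaned.append(preprocessing.wavelet_denoise(preprocessing.amplify(e, config.gain), config.denoise))
    logger.info("preprocessed %d epochs (gain=%g, wavelet=%s)", len(cleaned), config.gain, config.denoise.wavelet_name)
    return signal_io.GestureDataset(
        epochs=cleaned,
        vocabulary=dataset.vocabulary,
        vocabulary_name=dataset.vocabulary_name,
        split=dict(dataset.split),
    )


@_stage("decompose")
def _decompose(dataset: signal_io.GestureDataset, config: PipelineConfig) -> list[IMFSet]:
    sets = []
    for e in dataset:
        logger.debug("decompose %s", _epoch_id(e))
        sets.append(emd_decompose(e, config.emd))
    logger.info("decomposed %d epochs (mean IMFs %.1f)", len(sets), np.mean([len(s) for s in sets]))
    return sets


@_stage("featurize")
def _featurize(
    dataset: signal_io.GestureDataset, imfsets: list[IMFSet], config: PipelineConfig
) -> list[features.FeatureVector]:
    return [
        features.extract_features(s, config.emd.max_imfs, label=e.label, convention=config.feature_convention)
        for e, s in zip(dataset, imfsets)
    ]


@_stage("train")
def _train(
    train_vectors: list[features.FeatureVector], vocabulary: tuple[str, ...], config: PipelineConfig
) -> dnn.NetworkParams:
    index = {label: i for i, label in enumerate(vocabulary)}
    X = np.array([v.values for v in train_vectors])
    y = np.array([index[v.label] for v in train_vectors])
    arch = [X.shape[1], 64, 32, len(vocabulary)]
    logger.info("training %s on %d epochs", arch, len(train_vectors))
    return dnn.train(X, y, layer_sizes=arch, config=config.train)


@_stage("evaluate")
def _evaluate(
    params: dnn.NetworkParams,
    test_vectors: list[features.FeatureVector],
    vocabulary: tuple[str, ...],
) -> tuple[ConfusionMatrix, MetricsReport]:
    if not test_vectors:
        raise ValidationError("test split is empty; refusing to evaluate")
    X = np.array([v.values for v in test_vectors])
    predicted, _ = dnn.predict(params, X)
    y_pred = [vocabulary[i] for i in np.atleast_1d(predicted)]
    y_true = [v.label for v in test_vectors]
    cm = confusion_matrix(y_true, y_pred, vocabulary)
    return cm, compute_metrics(cm)


def run_pipeline(config: PipelineConfig) -> MetricsReport:
    """Run the full gesture-classification pipeline; see the module docstring."""
    config = config.resolved()
    out = Path(config.output_dir) if config.output_dir else None
    pkg_logger = logging.getLogger("emghht")
    prev_level = pkg_logger.level
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "pipeline.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        pkg_logger.addHandler(handler)
        if pkg_logger.getEffectiveLevel() > logging.INFO:
            pkg_logger.setLevel(logging.INFO)

    try:
        dataset = _acquire(config)
        if out is not None:
            signal_io.write_epochs(dataset, out / "dataset.npz", format="npz")
        cleaned = _preprocess(dataset, config)
        if out is not None:
            signal_io.write_epochs(cleaned, out / "denoised.npz", format="npz")
        imfsets = _decompose(cleaned, config)
        if out is not None:
            write_imfsets(imfsets, out / "imfs.npz")
        vectors = _featurize(cleaned, imfsets, config)

        pairs = list(zip(cleaned.epochs, vectors))
        train_trials = set(config.train_trials)
        present = cleaned.trial_indices()
        if not train_trials <= present:
            raise PipelineStageError("split", f"train_trials {sorted(train_trials)} not among trials {sorted(present)}")
        train_vec = [v for e, v in pairs if e.trial_index in train_trials]
        test_vec = [v for e, v in pairs if e.trial_index not in train_trials]
        logger.info("split: %d train / %d test epochs (train trials %s)", len(train_vec), len(test_vec), sorted(train_trials))
        if out is not None:
            features.feature_frame(vectors).to_csv(out / "features.csv", index=False)

        params = _train(train_vec, cleaned.vocabulary, config)
        if out is not None:
            dnn.save_params(params, out / "model.npz")
        cm, report = _evaluate(params, test_vec, cleaned.vocabulary)
        logger.info("test accuracy %.4f", report.overall_accuracy)

        if out is not None:
            cm.to_frame().to_csv(out / "confusion.csv")
            (out / "report.json").write_text(report.to_json(indent=1))
            (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, default=str))
        return report
    finally:
        if out is not None:
            pkg_logger.removeHandler(handler)
            pkg_logger.setLevel(prev_level)
            handler.close()


def write_imfsets(imfsets: list[IMFSet], path) -> None:
    """Serialize IMF sets to the binary container with a JSON sidecar."""
    path = Path(path)
    arrays = {}
    meta = []
    for i, s in enumerate(imfsets):
        for k, imf in enumerate(s.imfs):
            arrays[f"set{i:05d}_imf{k:02d}"] = imf
        arrays[f"set{i:05d}_residue"] = s.residue
        meta.append(
            {
                "n_imfs": len(s.imfs),
                "sift_counts": s.sift_counts,
                "stop_reasons": s.stop_reasons,
                "final_sigmas": s.final_sigmas,
                "source_length": s.source_length,
            }
        )
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    Path(str(path) + ".json").write_text(json.dumps({"sets": meta}, indent=1))


def read_imfsets(path) -> list[IMFSet]:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    out = []
    with np.load(path) as archive:
        for i, m in enumerate(meta["sets"]):
            out.append(
                IMFSet(
                    imfs=[archive[f"set{i:05d}_imf{k:02d}"] for k in range(m["n_imfs"])],
                    residue=archive[f"set{i:05d}_residue"],
                    sift_counts=list(m["sift_counts"]),
                    source_length=int(m["source_length"]),
                    stop_reasons=list(m["stop_reasons"]),
                    final_sigmas=list(m["final_sigmas"]),
                )
            )
    return out
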