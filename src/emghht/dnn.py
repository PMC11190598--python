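"""Feedforward classifier: leaky-ReLU hidden layers, softmax output,
mini-batch gradient descent on cross-entropy with from-scratch backprop.

The network maps a per-epoch feature vector through dense hidden layers
with the leaky rectifier f(x) = x for x > 0 and 0.01 x otherwise, and a
softmax output p_j = exp(x_j) / sum_k exp(x_k) giving one probability per
gesture class.  Training follows plain stochastic gradient descent: weights
are seeded-random-initialised (uniform, scaled by 1/sqrt(fan-in)), batches
of labelled feature vectors are drawn, the error signal between predicted
and target distributions is backpropagated, and a learning-rate-sized
portion of the gradient is subtracted from each parameter.  Everything is
float64 numpy on one thread, so a fixed seed reproduces training bit for
bit.

Feature standardization (z-score per feature, fitted on the training set)
is folded into the returned parameters so prediction applies it
transparently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DivergedTrainingError, ValidationError


def lrelu(x):
    """Leaky rectifier: x for x > 0, 0.01 x otherwise."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, 0.01 * x)


def _lrelu_grad(x):
    return np.where(np.asarray(x) > 0, 1.0, 0.01)


def softmax(logits):
    """Probability vector exp(x_j)/sum exp(x_k), computed shift-invariantly."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


@dataclass
class NetworkParams:
    """Weights and biases of the trained classifier.

    feature_mean/feature_std, when set, standardize inputs before the first
    layer; loss_history records the mean training loss per epoch.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int = 0
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValidationError("network needs at least input and output layers")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.layer_sizes[i + 1], self.layer_sizes[i]):
                raise ValidationError(f"weight {i} has shape {w.shape}, expected "
                                      f"({self.layer_sizes[i + 1]}, {self.layer_sizes[i]})")
            if b.shape != (self.layer_sizes[i + 1],):
                raise ValidationError(f"bias {i} has shape {b.shape}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 400
    batch_size: int = 16
    loss: str = "cross-entropy"
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.loss != "cross-entropy":
            raise ValidationError(f"unsupported loss {self.loss!r}")


def init_params(layer_sizes, seed: int = 0) -> NetworkParams:
    """Seeded random initialization: uniform weights scaled by 1/sqrt(fan-in)."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    params = NetworkParams(layer_sizes=list(layer_sizes), weights=weights, biases=biases, seed=seed)
    params.validate()
    return params


def _standardize(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    if params.feature_mean is None:
        return X
    return (X - params.feature_mean) / params.feature_std


def _forward_cache(params: NetworkParams, X: np.ndarray):
    """Activations and pre-activations for every layer; X is (n, d)."""
    activations = [X]
    pre = []
    a = X
    last = len(params.weights) - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w.T + b
        pre.append(z)
        a = softmax(z) if i == last else lrelu(z)
        activations.append(a)
    return pre, activations


def forward(params: NetworkParams, features) -> np.ndarray:
    """Class-probability vector (or matrix, for a batch of rows)."""
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != params.layer_sizes[0]:
        raise ValidationError(
            f"feature length {X.shape[1]} does not match input layer {params.layer_sizes[0]}"
        )
    _, activations = _forward_cache(params, _standardize(params, X))
    probs = activations[-1]
    return probs[0] if single else probs


def loss_and_grads(params: NetworkParams, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradients w.r.t. every weight and bias.

    y holds integer class indices.  Softmax and cross-entropy combine into
    the standard (p - onehot)/n error signal at the output layer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    pre, activations = _forward_cache(params, X)
    probs = activations[-1]
    eps = 1e-300  # guard the log only; probabilities themselves are untouched
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))

    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads_w, grads_b = [], []
    for i in range(len(params.weights) - 1, -1, -1):
        grads_w.append(delta.T @ activations[i])
        grads_b.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ params.weights[i]) * _lrelu_grad(pre[i - 1])
    return loss, grads_w[::-1], grads_b[::-1]


def train(
    X,
    y,
    layer_sizes=None,
    config: TrainConfig = TrainConfig(),
    hidden_sizes=(64, 32),
) -> NetworkParams:
    """Mini-batch gradient descent on cross-entropy; fixed seed, fixed result.

    X is (n_samples, n_features); y holds integer class indices 0..k-1.
    When ``layer_sizes`` is omitted, the architecture is input -> 64 -> 32 ->
    n_classes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValidationError("feature matrix and label vector lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("training requires at least 2 classes present")
    n_classes = int(classes.max()) + 1
    if layer_sizes is None:
        layer_sizes = [X.shape[1], *hidden_sizes, n_classes]
    if layer_sizes[0] != X.shape[1]:
        raise ValidationError("input layer size does not match feature length")
    if layer_sizes[-1] < n_classes:
        raise ValidationError("output layer smaller than the number of classes")

    params = init_params(layer_sizes, seed=config.seed)
    if config.standardize_features:
        params.feature_mean = X.mean(axis=0)
        params.feature_std = np.maximum(X.std(axis=0), 1e-12)
    Xs = _standardize(params, X)

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    lr = config.learning_rate
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads_w, grads_b = loss_and_grads(
                _strip_standardizer(params), Xs[batch], y[batch]
            )
            if not np.isfinite(loss):
                raise DivergedTrainingError(
                    f"training loss became non-finite; reduce learning_rate={lr}"
                )
            for w, gw in zip(params.weights, grads_w):
                w -= lr * gw
            for b, gb in zip(params.biases, grads_b):
                b -= lr * gb
            epoch_losses.append(loss)
        params.loss_history.append(float(np.mean(epoch_losses)))
    return params


def _strip_standardizer(params: NetworkParams) -> NetworkParams:
    """View of the params without input standardization (already applied)."""
    return NetworkParams(
        layer_sizes=params.layer_sizes,
        weights=params.weights,
        biases=params.biases,
        seed=params.seed,
    )


def predict(params: NetworkParams, features):
    """Argmax label index plus the probability vector; ties -> lowest index."""
    probs = forward(params, features)
    if probs.ndim == 1:
        return int(np.argmax(probs)), probs
    return np.argmax(probs, axis=1), probs


def save_params(params: NetworkParams, path) -> None:
    """Serialize to the binary container plus a JSON sidecar."""
    path = Path(path)
    arrays = {f"w{i}": w for i, w in enumerate(params.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(params.biases)})
    if params.feature_mean is not None:
        arrays["feature_mean"] = params.feature_mean
        arrays["feature_std"] = params.feature_std
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    meta = {
        "layer_sizes": params.layer_sizes,
        "seed": params.seed,
        "loss_history": params.loss_history,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_params(path) -> NetworkParams:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path) as archive:
        n_layers = len(meta["layer_sizes"]) - 1
        params = NetworkParams(
            layer_sizes=list(meta["layer_sizes"]),
            weights=[archive[f"w{i}"] for i in range(n_layers)],
            biases=[archive[f"b{i}"] for i in range(n_layers)],
            seed=int(meta["seed"]),
            feature_mean=archive["feature_mean"] if "feature_mean" in archive else None,
            feature_std=archive["feature_std"] if "feature_std" in archive else None,
            loss_history=list(meta.get("loss_history", [])),
        )
    params.validate()
    return params
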