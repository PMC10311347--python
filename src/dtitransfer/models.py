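"""The FNN-2 reference classifier and the shallow SVM model.

The deep model is a two-hidden-layer feed-forward network (input 300 ->
1200 -> 300 -> 2-way softmax) trained with mini-batch Adam on cross-entropy.
It is the common backbone for scratch training, fine-tuning and the frozen
transfer modes: every layer can be frozen individually, and frozen layers are
guaranteed bit-identical across training.

All arithmetic is float32; given a seed, initialization and training are
fully deterministic, so checkpoints and repeated runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import DimensionError

LAYER_NAMES = ("L1", "L2", "Lout")


class LabeledVectors(NamedTuple):
    """A featurized dataset: row-per-compound matrix plus 0/1 activity labels."""

    X: np.ndarray  # (n, d) float32
    y: np.ndarray  # (n,) int, 1 = active
    family: str = ""

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class FNNConfig:
    """Hyperparameters of the FNN-2 classifier.

    Defaults are the reference configuration: two hidden layers of 1200 and
    300 units, learning rate 1e-4, 100 epochs, batch size 256. Activation
    (ReLU), optimizer (Adam) and loss (softmax cross-entropy) are fixed
    architectural choices exposed here only through their hyperparameters.
    """

    input_dim: int = 300
    hidden_sizes: tuple[int, int] = (1200, 300)
    n_classes: int = 2
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("layer sizes must be positive")
        if len(self.hidden_sizes) != 2:
            raise ValueError("the reference architecture has exactly two hidden layers")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative (0 = evaluate-only)")

    def layer_dims(self) -> list[tuple[int, int]]:
        h1, h2 = self.hidden_sizes
        return [(self.input_dim, h1), (h1, h2), (h2, self.n_classes)]


@dataclass
class FNNParams:
    """Per-layer weights/biases with a provenance tag.

    ``weights[name]``/``biases[name]`` for name in ("L1", "L2", "Lout").
    Provenance records whether the parameters come from seeded scratch
    initialization, Stage-I pre-training, or Stage-II fine-tuning.
    """

    weights: dict[str, np.ndarray]
    biases: dict[str, np.ndarray]
    provenance: str = "scratch"

    def copy(self) -> "FNNParams":
        return FNNParams(
            weights={k: v.copy() for k, v in self.weights.items()},
            biases={k: v.copy() for k, v in self.biases.items()},
            provenance=self.provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FNNParams):
            return NotImplemented
        return (
            set(self.weights) == set(other.weights)
            and all(np.array_equal(self.weights[k], other.weights[k]) for k in self.weights)
            and all(np.array_equal(self.biases[k], other.biases[k]) for k in self.biases)
        )

    @property
    def input_dim(self) -> int:
        return self.weights["L1"].shape[0]


@dataclass
class TrainRecord:
    """Per-epoch mean training loss; ``losses[0]`` is the first-epoch loss."""

    losses: list[float] = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.losses)


def init_fnn(config: FNNConfig) -> FNNParams:
    """Seeded He-normal initialization of all three layers (provenance 'scratch')."""
    rng = np.random.default_rng(config.seed)
    weights, biases = {}, {}
    for name, (fan_in, fan_out) in zip(LAYER_NAMES, config.layer_dims()):
        std = np.sqrt(2.0 / fan_in)
        weights[name] = (rng.standard_normal((fan_in, fan_out)) * std).astype(np.float32)
        biases[name] = np.zeros(fan_out, dtype=np.float32)
    return FNNParams(weights=weights, biases=biases, provenance="scratch")


def _as_matrix(vectors: np.ndarray, input_dim: int) -> np.ndarray:
    X = np.asarray(vectors, dtype=np.float32)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != input_dim:
        raise DimensionError(
            f"input dimension {X.shape[1]} does not match model input {input_dim}"
        )
    return X


def _forward(params: FNNParams, X: np.ndarray):
    """Return (logits, h1, h2) with ReLU hidden activations."""
    h1 = np.maximum(X @ params.weights["L1"] + params.biases["L1"], 0.0)
    h2 = np.maximum(h1 @ params.weights["L2"] + params.biases["L2"], 0.0)
    logits = h2 @ params.weights["Lout"] + params.biases["Lout"]
    return logits, h1, h2


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_fnn(
    params: FNNParams,
    data: tuple[np.ndarray, np.ndarray],
    config: FNNConfig,
    freeze: Sequence[str] = (),
) -> tuple[FNNParams, TrainRecord]:
    """Mini-batch Adam training on softmax cross-entropy.

    ``freeze`` names layers whose parameters must stay bit-identical; at least
    one layer must remain trainable. The input ``params`` object is never
    mutated — a trained copy is returned together with the loss record.
    Shuffling, and hence the whole trajectory, is seeded by ``config.seed``.
    """
    freeze = frozenset(freeze)
    unknown = freeze - set(LAYER_NAMES)
    if unknown:
        raise ValueError(f"unknown layer names in freeze mask: {sorted(unknown)}")
    if freeze == set(LAYER_NAMES):
        raise ValueError("all layers frozen: nothing to train")

    X_raw, y_raw = data
    X = _as_matrix(np.asarray(X_raw), params.input_dim)
    y = np.asarray(y_raw, dtype=np.int64).ravel()
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")

    p = params.copy()
    trainable = [n for n in LAYER_NAMES if n not in freeze]
    # Backprop only needs to reach the deepest frozen prefix boundary.
    deepest_needed = min(LAYER_NAMES.index(n) for n in trainable)

    lr = np.float32(config.learning_rate)
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
    m = {n: (np.zeros_like(p.weights[n]), np.zeros_like(p.biases[n])) for n in trainable}
    v = {n: (np.zeros_like(p.weights[n]), np.zeros_like(p.biases[n])) for n in trainable}

    rng = np.random.default_rng(config.seed)
    n = len(X)
    step = 0
    record = TrainRecord()
    for _epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits, h1, h2 = _forward(p, xb)
            probs = _softmax(logits.astype(np.float64))
            batch_loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-300))
            epoch_loss += batch_loss * len(yb)

            dlogits = probs.astype(np.float32)
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= np.float32(len(yb))

            grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            if "Lout" in m:
                grads["Lout"] = (h2.T @ dlogits, dlogits.sum(axis=0))
            if deepest_needed <= 1:
                dh2 = (dlogits @ p.weights["Lout"].T) * (h2 > 0)
                if "L2" in m:
                    grads["L2"] = (h1.T @ dh2, dh2.sum(axis=0))
                if deepest_needed == 0:
                    dh1 = (dh2 @ p.weights["L2"].T) * (h1 > 0)
                    grads["L1"] = (xb.T @ dh1, dh1.sum(axis=0))

            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for name in trainable:
                gw, gb = grads[name]
                mw, mb = m[name]
                vw, vb = v[name]
                mw *= b1
                mw += (1 - b1) * gw
                mb *= b1
                mb += (1 - b1) * gb
                vw *= b2
                vw += (1 - b2) * gw * gw
                vb *= b2
                vb += (1 - b2) * gb * gb
                p.weights[name] -= lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
                p.biases[name] -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        record.losses.append(float(epoch_loss / n))

    p.provenance = "finetuned" if params.provenance in ("pretrained", "finetuned") else "scratch"
    return p, record


def predict_fnn(params: FNNParams, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels (argmax) and active-class probabilities (softmax column 1)."""
    X = _as_matrix(vectors, params.input_dim)
    logits, _, _ = _forward(params, X)
    probs = _softmax(logits.astype(np.float64))
    return probs.argmax(axis=1), probs[:, 1]


def extract_features(params: FNNParams, vectors: np.ndarray) -> np.ndarray:
    """Second-hidden-layer activations (the 300-d learned representation)."""
    X = _as_matrix(vectors, params.input_dim)
    _, _, h2 = _forward(params, X)
    return h2


@dataclass(frozen=True)
class ShallowHyper:
    """SVM hyperparameters (RBF kernel, C=1, variance-scaled gamma by default)."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class ShallowModel:
    kind: str
    estimator: SVC
    hyper: ShallowHyper


def fit_shallow(
    features: np.ndarray, labels: np.ndarray, hyper: ShallowHyper | None = None
) -> ShallowModel:
    """Fit the shallow SVM on feature vectors; requires both classes present."""
    hyper = hyper or ShallowHyper()
    y = np.asarray(labels).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("shallow model needs at least one example of each class")
    est = SVC(kernel=hyper.kernel, C=hyper.C, gamma=hyper.gamma)
    est.fit(np.asarray(features, dtype=np.float64), y)
    return ShallowModel(kind="svm", estimator=est, hyper=hyper)


def predict_shallow(model: ShallowModel, features: np.ndarray) -> np.ndarray:
    return model.estimator.predict(np.asarray(features, dtype=np.float64))


def shallow_scores(model: ShallowModel, features: np.ndarray) -> np.ndarray:
    """Signed distance to the margin; monotone in active-class confidence."""
    return model.estimator.decision_function(np.asarray(features, dtype=np.float64))


def scratch_config(config: FNNConfig, seed: int) -> FNNConfig:
    """The same hyperparameters with a different seed (for per-repeat scratch runs)."""
    return replace(config, seed=seed)
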