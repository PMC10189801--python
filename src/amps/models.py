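"""The four classifiers and their training/prediction machinery.

* ``amps_cnn`` — one 1D conv layer (16 channels, kernel ``4 + a``) + ReLU,
  flatten, dense 128 + ReLU + dropout 0.5, dense 1 + sigmoid.  Input is the
  ``W_s x (4 + a)`` encoded window.
* ``neighbor_mlp`` — four dense layers (20, 16, 8, 1 nodes), hidden ReLU,
  dropout 0.5, sigmoid output.  Input is the length-``W_p`` vector of
  neighboring methylation levels.
* ``combined`` — two conv layers on the window, flattened and concatenated
  with the neighbor vector, then dense 16, 8, 1.
* ``random_forest`` — scikit-learn baseline, 50 trees, unlimited depth, on
  the flattened window.

All networks are trained with plain SGD on binary cross-entropy (batch 32,
20 epochs, lr 0.001 by default); the epoch with the best validation accuracy
supplies the final weights.  The classification threshold is 0.5 (inclusive)
on the sigmoid output.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .datasets import Dataset, DatasetSplit

KINDS = ("amps_cnn", "neighbor_mlp", "combined", "random_forest")

NEIGHBOR_WIDTHS = (20, 16, 8)
COMBINED_WIDTHS = (16, 8)
CONV_CHANNELS = 16
DENSE_WIDTH = 128
DROPOUT = 0.5


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 0.001
    momentum: float = 0.0
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs <= 0 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be > 0")


@dataclass
class ModelSpec:
    kind: str
    W_s: Optional[int] = None
    a: Optional[int] = None
    W_p: Optional[int] = None
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class Model:
    """An untrained or trained classifier: spec plus realized estimator."""

    spec: ModelSpec
    net: object  # nn.Sequential / nn.TwoBranch / RandomForestClassifier

    @property
    def kind(self) -> str:
        return self.spec.kind

    @property
    def n_params(self) -> int:
        if self.kind == "random_forest":
            raise TypeError("random forest has no fixed parameter count")
        return self.net.n_params


@dataclass
class TrainedModel:
    model: Model
    config: TrainConfig
    history: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


def conv_output_length(W_s: int, kernel: int) -> int:
    return W_s - kernel + 1


def build_amps_cnn(W_s: int, a: int = 0, seed: int = 0) -> Model:
    """Sequence(+annotation) CNN; kernel width is tied to the input width."""
    if W_s <= 0 or a < 0:
        raise ValueError("W_s must be positive and a non-negative")
    rng = np.random.default_rng(seed)
    kernel = 4 + a
    flat = CONV_CHANNELS * conv_output_length(W_s, kernel)
    net = nn.Sequential([
        nn.Conv1D(4 + a, CONV_CHANNELS, kernel, rng),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(flat, DENSE_WIDTH, rng),
        nn.ReLU(),
        nn.Dropout(DROPOUT),
        nn.Dense(DENSE_WIDTH, 1, rng, relu_fan=False),
    ])
    return Model(ModelSpec("amps_cnn", W_s=W_s, a=a, init_seed=seed), net)


def build_neighbor_mlp(W_p: int = 20, seed: int = 0,
                       widths: Tuple[int, ...] = NEIGHBOR_WIDTHS) -> Model:
    """Neighbor-level MLP: dense 20, 16, 8, 1."""
    if W_p != widths[0]:
        raise ValueError(
            f"input length {W_p} does not match first layer width "
            f"{widths[0]}; pass rescaled widths explicitly")
    rng = np.random.default_rng(seed)
    layers: List[nn.Layer] = []
    prev = W_p
    for w in widths:
        layers += [nn.Dense(prev, w, rng), nn.ReLU(), nn.Dropout(DROPOUT)]
        prev = w
    layers.append(nn.Dense(prev, 1, rng, relu_fan=False))
    return Model(ModelSpec("neighbor_mlp", W_p=W_p, init_seed=seed),
                 nn.Sequential(layers))


def build_combined(W_s: int, a: int = 0, W_p: int = 20, seed: int = 0) -> Model:
    """Sequence + annotation + neighbor-level network.

    The two conv layers mirror the sequence CNN's conv layer (16 channels,
    kernel ``4 + a``, stride 1, no padding); the concatenated vector feeds
    dense layers of 16, 8 and 1 node.
    """
    rng = np.random.default_rng(seed)
    kernel = 4 + a
    trunk: List[nn.Layer] = [
        nn.Conv1D(4 + a, CONV_CHANNELS, kernel, rng),
        nn.ReLU(),
        nn.Conv1D(CONV_CHANNELS, CONV_CHANNELS, kernel, rng),
        nn.ReLU(),
        nn.Flatten(),
    ]
    flat = CONV_CHANNELS * conv_output_length(
        conv_output_length(W_s, kernel), kernel)
    head: List[nn.Layer] = []
    prev = flat + W_p
    for w in COMBINED_WIDTHS:
        head += [nn.Dense(prev, w, rng), nn.ReLU(), nn.Dropout(DROPOUT)]
        prev = w
    head.append(nn.Dense(prev, 1, rng, relu_fan=False))
    return Model(ModelSpec("combined", W_s=W_s, a=a, W_p=W_p, init_seed=seed),
                 nn.TwoBranch(trunk, head))


def build_random_forest(seed: int = 0) -> Model:
    """Baseline: 50 trees, unlimited depth, other settings at defaults."""
    clf = RandomForestClassifier(n_estimators=50, max_depth=None,
                                 random_state=seed)
    return Model(ModelSpec("random_forest", init_seed=seed), clf)


def _inputs(kind: str, dataset: Dataset, idx: Optional[np.ndarray] = None):
    take = (lambda arr: arr if idx is None else arr[idx])
    if kind == "neighbor_mlp":
        if dataset.V is None:
            raise ValueError("dataset lacks neighbor vectors")
        return take(dataset.V).astype(np.float32)
    if dataset.X is None:
        raise ValueError("dataset lacks encoded windows")
    X = take(dataset.X).astype(np.float32)
    if kind == "combined":
        if dataset.V is None:
            raise ValueError("combined model needs neighbor vectors")
        return (X, take(dataset.V).astype(np.float32))
    if kind == "random_forest":
        return X.reshape(len(X), -1)
    return X


def _forward_logits(trained_or_model, dataset: Dataset,
                    batch_size: int = 512) -> np.ndarray:
    model = trained_or_model.model if isinstance(trained_or_model, TrainedModel) \
        else trained_or_model
    n = len(dataset)
    logits = np.empty(n, dtype=np.float64)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        out = model.net.forward(_inputs(model.kind, dataset, idx), train=False)
        logits[idx] = out[:, 0]
    return logits


def predict(trained_or_model, dataset: Dataset,
            batch_size: int = 512) -> Tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls (probability >= 0.5 -> methylated)."""
    model = trained_or_model.model if isinstance(trained_or_model, TrainedModel) \
        else trained_or_model
    if len(dataset) == 0:
        return np.empty(0), np.empty(0, dtype=np.uint8)
    if model.kind == "random_forest":
        X = _inputs("random_forest", dataset)
        proba = model.net.predict_proba(X)
        pos_col = int(np.flatnonzero(model.net.classes_ == 1)[0]) \
            if 1 in model.net.classes_ else None
        probs = proba[:, pos_col] if pos_col is not None else np.zeros(len(X))
    else:
        probs = nn.sigmoid(_forward_logits(model, dataset, batch_size))
    return probs, (probs >= 0.5).astype(np.uint8)


def accuracy(trained_or_model, dataset: Dataset) -> float:
    _, calls = predict(trained_or_model, dataset)
    return float(np.mean(calls == dataset.y))


def train(model: Model, split: DatasetSplit,
          config: Optional[TrainConfig] = None) -> TrainedModel:
    """Fit on the train partition; select the best epoch by validation
    accuracy.  Fully deterministic under ``config.seed``."""
    config = config or TrainConfig()
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ValueError("train and validation partitions must be nonempty")

    if model.kind == "random_forest":
        X = _inputs("random_forest", split.train)
        model.net.fit(X, split.train.y)
        trained = TrainedModel(model, config, best_epoch=0)
        trained.history = [{"epoch": 0, "train_loss": float("nan"),
                            "val_accuracy": accuracy(model, split.validation)}]
        return trained

    rng = np.random.default_rng(config.seed)
    optimizer = nn.SGD(model.net, lr=config.learning_rate,
                       momentum=config.momentum)
    n = len(split.train)
    y_train = split.train.y.astype(np.float32)
    history: List[Dict[str, float]] = []
    best_acc, best_epoch, best_state = -1.0, 0, model.net.state()

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            inputs = _inputs(model.kind, split.train, idx)
            logits = model.net.forward(inputs, train=True, rng=rng)
            loss, dlogits = nn.bce_with_logits(logits[:, 0], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start}")
            model.net.backward(dlogits[:, None])
            optimizer.step()
            epoch_loss += loss * len(idx)
        val_acc = accuracy(model, split.validation)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                        "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.net.state()

    model.net.load_state(best_state)
    return TrainedModel(model, config, history=history, best_epoch=best_epoch)


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Serialize spec + config + history + weights to one file."""
    path = Path(path)
    meta = {"spec": asdict(trained.spec), "config": asdict(trained.config),
            "history": trained.history, "best_epoch": trained.best_epoch}
    if trained.model.kind == "random_forest":
        with open(path, "wb") as fh:
            pickle.dump({"meta": meta, "estimator": trained.model.net}, fh)
        return
    arrays = {}
    for i, params in enumerate(trained.model.net.state()):
        for name, value in params.items():
            arrays[f"layer{i}.{name}"] = value
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic != b"PK\x03\x04":  # not a zip -> pickled random forest
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        meta = payload["meta"]
        model = Model(ModelSpec(**meta["spec"]), payload["estimator"])
    else:
        data = np.load(path)
        meta = json.loads(data["__meta__"].tobytes().decode())
        spec = ModelSpec(**meta["spec"])
        model = _rebuild(spec)
        state = model.net.state()
        for i, params in enumerate(state):
            for name in params:
                params[name] = data[f"layer{i}.{name}"]
        model.net.load_state(state)
    trained = TrainedModel(model, TrainConfig(**meta["config"]),
                           history=meta["history"],
                           best_epoch=meta["best_epoch"])
    return trained


def _rebuild(spec: ModelSpec) -> Model:
    if spec.kind == "amps_cnn":
        return build_amps_cnn(spec.W_s, spec.a, seed=spec.init_seed)
    if spec.kind == "neighbor_mlp":
        return build_neighbor_mlp(spec.W_p, seed=spec.init_seed)
    if spec.kind == "combined":
        return build_combined(spec.W_s, spec.a, spec.W_p, seed=spec.init_seed)
    return build_random_forest(seed=spec.init_seed)
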