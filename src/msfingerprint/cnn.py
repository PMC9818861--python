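"""The shallow convolutional classifier for spectral-matrix images.

The architecture follows the method's description: a small stack of
convolution layers (four by default) interspersed with maximum-pooling
layers, closed by a flatten and a single sigmoid unit that emits the
probability of the configured positive class. The model is deliberately
simple — no hyperparameter search exists in this package; the config
defaults are the only tuning surface, which is the method's guard against
overfitting the handful of cultivars available per class.

The probability is clipped to [1e-6, 1 - 1e-6] before it leaves the model:
downstream scores are linear in the log odds, which diverge at 0 and 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    Conv2DSame,
    Dense,
    Flatten,
    MaxPool,
    ReLU,
    Sequential,
    bce_loss,
    sigmoid,
)
from .errors import ShapeMismatchError
from .matrixify import SpectralMatrix

PROB_EPS = 1e-6


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training settings.

    ``filters_per_layer`` must have one entry per convolution layer. The
    kernel must be odd in both dimensions (stride-1 'same' convolution).
    ``early_stop_loss`` ends training once the epoch-mean binary
    cross-entropy falls below it; set to 0 to always run ``epochs`` epochs.
    """

    n_conv_layers: int = 4
    filters_per_layer: tuple[int, ...] = (8, 16, 32, 64)
    kernel_size: tuple[int, int] = (3, 3)
    pool_size: tuple[int, int] = (2, 2)
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    positive_class: str = "A"
    early_stop_loss: float = 0.005

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("need at least one convolution layer")
        if len(self.filters_per_layer) != self.n_conv_layers:
            raise ValueError("filters_per_layer must list one size per conv layer")
        if any(f < 1 for f in self.filters_per_layer):
            raise ValueError("filter counts must be positive")
        if any(k < 1 for k in self.kernel_size) or any(p < 1 for p in self.pool_size):
            raise ValueError("kernel and pool sizes must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainedModel:
    """A (possibly untrained) network bound to a fixed input shape."""

    net: Sequential
    config: CnnConfig
    input_shape: tuple[int, int]
    fold_index: int | None = None
    loss_trace: list[float] = field(default_factory=list)
    trained: bool = False

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params())}
        meta = {
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "fold_index": self.fold_index,
            "loss_trace": self.loss_trace,
            "trained": self.trained,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            for key in ("filters_per_layer", "kernel_size", "pool_size"):
                cfg_dict[key] = tuple(cfg_dict[key])
            config = CnnConfig(**cfg_dict)
            model = build_model(config, tuple(meta["input_shape"]))
            for i, p in enumerate(model.net.params()):
                p[...] = data[f"p{i}"]
        model.fold_index = meta["fold_index"]
        model.loss_trace = list(meta["loss_trace"])
        model.trained = meta["trained"]
        return model


def _pooled_shape(shape: tuple[int, int], config: CnnConfig) -> tuple[int, int]:
    h, w = shape
    for _ in range(config.n_conv_layers):
        h //= config.pool_size[0]
        w //= config.pool_size[1]
    return h, w


def build_model(config: CnnConfig, input_shape: tuple[int, int]) -> TrainedModel:
    """Assemble the (untrained) network for matrices of ``input_shape``.

    Raises a configuration error when the image is too small to survive the
    pooling cascade, naming the minimal admissible shape.
    """
    if input_shape[0] < 1 or input_shape[1] < 1:
        raise ValueError("input shape must be positive")
    h, w = _pooled_shape(input_shape, config)
    if h < 1 or w < 1:
        min_shape = (
            config.pool_size[0] ** config.n_conv_layers,
            config.pool_size[1] ** config.n_conv_layers,
        )
        raise ValueError(
            f"input shape {input_shape} too small for {config.n_conv_layers} "
            f"pooling stages; minimal admissible shape is {min_shape}"
        )
    rng = np.random.default_rng(config.seed)
    layers: list = []
    c_in = 1
    for i, n_filters in enumerate(config.filters_per_layer):
        layers.append(
            Conv2DSame(c_in, n_filters, config.kernel_size, rng, first_layer=(i == 0))
        )
        layers.append(ReLU())
        layers.append(MaxPool(config.pool_size))
        c_in = n_filters
    layers.append(Flatten())
    layers.append(Dense(h * w * c_in, 1, rng))
    return TrainedModel(net=Sequential(layers), config=config, input_shape=tuple(input_shape))


def _stack(matrices: list[SpectralMatrix], input_shape: tuple[int, int]) -> np.ndarray:
    for m in matrices:
        if not m.normalized:
            raise ValueError(f"matrix {m.sample_id!r} is not z-normalized")
        if m.shape != tuple(input_shape):
            raise ShapeMismatchError(
                f"matrix {m.sample_id!r} has shape {m.shape}, model expects {input_shape}"
            )
    return np.stack([m.values for m in matrices]).astype(np.float32)[..., None]


def train(
    model: TrainedModel, matrices: list[SpectralMatrix], labels: list[str]
) -> TrainedModel:
    """Fit the network by minimizing binary cross-entropy with Adam.

    Labels are class names; the sigmoid output is the probability of
    ``model.config.positive_class``. Training order is shuffled per epoch
    from the config seed, so a run is reproducible.
    """
    if len(matrices) != len(labels):
        raise ValueError("matrices and labels must be aligned")
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")
    cfg = model.config
    x = _stack(matrices, model.input_shape)
    y = np.array(
        [1.0 if lab == cfg.positive_class else 0.0 for lab in labels], dtype=np.float32
    ).reshape(-1, 1)
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from init stream
    optimizer = Adam(model.net.params(), lr=cfg.learning_rate)
    n = len(matrices)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.net.forward(x[idx], train=True)
            p = sigmoid(logits)
            losses.append(bce_loss(p, y[idx]))
            model.net.backward((p - y[idx]) / len(idx))
            optimizer.step(model.net.grads())
        epoch_loss = float(np.mean(losses))
        model.loss_trace.append(epoch_loss)
        if epoch_loss < cfg.early_stop_loss:
            break
    model.trained = True
    return model


def predict_probabilities(
    model: TrainedModel, matrices: list[SpectralMatrix]
) -> np.ndarray:
    """Probabilities of the positive class, clipped inside (0, 1)."""
    x = _stack(matrices, model.input_shape)
    p = sigmoid(model.net.forward(x, train=False)).ravel()
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS).astype(np.float64)


def predict_probability(model: TrainedModel, matrix: SpectralMatrix) -> float:
    return float(predict_probabilities(model, [matrix])[0])
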