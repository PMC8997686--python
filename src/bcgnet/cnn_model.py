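"""The 24-layer 2D-CNN hypertension classifier.

The default architecture stacks, in order: eight strided (stride 2, "same"
padding) convolutions, five size-1/stride-1 max-pooling layers, three batch
normalizations, five dropouts, one flatten and two dense layers — 24 layers
in all, not counting the input.  All convolution and dense kernels carry an
L1(0.001) regularizer; the final layer is a 2-unit sigmoid (HC vs HPT) and
prediction is by argmax, ties resolving to HC.

Training uses Adam (learning rate 0.001, decay 0.01 interpreted as the
classical ``lr / (1 + decay * epochs_completed)`` schedule) with binary
cross-entropy against one-hot targets, batch size 100.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "Hyperparams",
    "ModelSpecError",
    "default_modelspec",
    "build_model",
    "CNNModel",
    "CLASSES",
]

CLASSES = ("HC", "HPT")  # index 0 is the negative class; argmax ties -> HC

#: required per-kind layer counts for a valid architecture
REQUIRED_COUNTS = {
    "conv2d": 8,
    "maxpool2d": 5,
    "batchnorm": 3,
    "dropout": 5,
    "flatten": 1,
    "dense": 2,
}


class ModelSpecError(ValueError):
    """Raised when an architecture spec violates the model invariants."""


def small_sample_hyperparams(epochs: int = 10) -> "Hyperparams":
    """Training configuration for datasets of a few hundred epochs.

    The stock defaults (batch 100, L1 0.001, 50 epochs) are calibrated for
    training sets of ~10^5 scalograms, where each epoch provides ~10^3
    gradient updates.  On a few hundred images that schedule yields so few
    updates that the constant L1 pull drives all kernels to zero before any
    feature can form, permanently silencing the ReLU stack.  This variant
    keeps the optimizer, loss and architecture but uses batch size 32 and
    disables the L1 penalty, which at this data volume regularizes far
    beyond its intent.
    """
    return Hyperparams(batch_size=32, l1=0.0, epochs=epochs)


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filters: int | None = None
    kernel: int | None = None
    stride: int | None = None
    pool_size: int | None = None
    rate: float | None = None
    units: int | None = None
    activation: str | None = None
    regularizer_l1: float | None = None


@dataclass(frozen=True)
class Hyperparams:
    batch_size: int = 100
    kernel_padding: str = "same"
    l1: float = 0.001
    optimizer: str = "adam"
    learning_rate: float = 0.001
    decay: float = 0.01
    loss: str = "binary_crossentropy"
    epochs: int = 50


@dataclass
class ModelSpec:
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int] = (32, 32, 1)

    def to_json(self) -> str:
        return json.dumps(
            {"input_shape": list(self.input_shape),
             "layers": [asdict(l) for l in self.layers]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(layers=[LayerSpec(**l) for l in d["layers"]],
                   input_shape=tuple(d["input_shape"]))


def _conv(filters: int, kernel: int, l1: float = 0.001) -> LayerSpec:
    return LayerSpec(kind="conv2d", filters=filters, kernel=kernel, stride=2,
                     activation="relu", regularizer_l1=l1)


def _pool() -> LayerSpec:
    return LayerSpec(kind="maxpool2d", pool_size=1, stride=1)


def default_modelspec(l1: float = 0.001, pool_size: int = 1) -> ModelSpec:
    """The default 24-layer stack (input layer not counted)."""
    pool = LayerSpec(kind="maxpool2d", pool_size=pool_size, stride=1)
    layers = [
        _conv(64, 3, l1), pool,
        LayerSpec(kind="batchnorm"), LayerSpec(kind="dropout", rate=0.25),
        _conv(64, 5, l1), pool,
        LayerSpec(kind="batchnorm"), LayerSpec(kind="dropout", rate=0.25),
        _conv(128, 7, l1),
        LayerSpec(kind="batchnorm"), LayerSpec(kind="dropout", rate=0.25),
        _conv(128, 7, l1), pool,
        LayerSpec(kind="dropout", rate=0.25),
        _conv(256, 3, l1), _conv(256, 3, l1), pool,
        _conv(64, 3, l1), _conv(64, 5, l1), pool,
        LayerSpec(kind="flatten"),
        LayerSpec(kind="dense", units=128, activation="relu", regularizer_l1=l1),
        LayerSpec(kind="dropout", rate=0.5),
        LayerSpec(kind="dense", units=2, activation="sigmoid", regularizer_l1=l1),
    ]
    return ModelSpec(layers=layers)


def validate_modelspec(spec: ModelSpec) -> None:
    counts: dict[str, int] = {k: 0 for k in REQUIRED_COUNTS}
    for i, l in enumerate(spec.layers):
        if l.kind not in REQUIRED_COUNTS:
            raise ModelSpecError(f"layer {i}: unknown kind {l.kind!r}")
        counts[l.kind] += 1
        if l.kind == "conv2d" and not (l.filters and l.kernel and l.stride):
            raise ModelSpecError(f"layer {i}: conv2d needs filters/kernel/stride")
        if l.kind == "dropout" and not (l.rate and 0 < l.rate < 1):
            raise ModelSpecError(f"layer {i}: dropout needs a rate in (0, 1)")
        if l.kind == "dense" and not l.units:
            raise ModelSpecError(f"layer {i}: dense needs units")
    for kind, want in REQUIRED_COUNTS.items():
        if counts[kind] != want:
            raise ModelSpecError(
                f"architecture must contain exactly {want} {kind} layers, found {counts[kind]}"
            )
    last = spec.layers[-1]
    if last.kind != "dense" or last.units != 2 or last.activation != "sigmoid":
        raise ModelSpecError("final layer must be a 2-unit sigmoid dense layer")


def spatial_trace(spec: ModelSpec) -> list[int]:
    """Spatial side length after each conv layer (ceil(n/stride) recurrence)."""
    side = spec.input_shape[0]
    out = []
    for l in spec.layers:
        if l.kind == "conv2d":
            side = -(-side // l.stride)
            out.append(side)
        elif l.kind == "maxpool2d":
            side = (side - l.pool_size) // l.stride + 1
    return out


class CNNModel:
    """A built network: seeded weights, Adam, forward/train/audit."""

    def __init__(self, spec: ModelSpec, hp: Hyperparams, seed: int):
        validate_modelspec(spec)
        self.spec, self.hp, self.seed = spec, hp, seed
        init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.layers: list[_nn.Layer] = []
        for l in spec.layers:
            if l.kind == "conv2d":
                self.layers.append(_nn.Conv2D(l.filters, l.kernel, l.stride,
                                              l.activation, l.regularizer_l1 or 0.0))
            elif l.kind == "maxpool2d":
                self.layers.append(_nn.MaxPool2D(l.pool_size, l.stride))
            elif l.kind == "batchnorm":
                self.layers.append(_nn.BatchNorm())
            elif l.kind == "dropout":
                self.layers.append(_nn.Dropout(l.rate, rng=self._dropout_rng))
            elif l.kind == "flatten":
                self.layers.append(_nn.Flatten())
            elif l.kind == "dense":
                self.layers.append(_nn.Dense(l.units, l.activation,
                                             l.regularizer_l1 or 0.0))
        shape = spec.input_shape
        for layer in self.layers:
            shape = layer.init_params(init_rng, shape)
        self.output_shape = shape
        self.optimizer = _nn.Adam(lr=hp.learning_rate, decay=hp.decay)

    # -- inference ---------------------------------------------------------
    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"batch shape {x.shape} incompatible with input {self.spec.input_shape}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode per-class scores in [0, 1], shape (n, 2)."""
        h = self._check_batch(x)
        for layer in self.layers:
            h = layer.forward(h, training=False)
        return h

    def predict_indices(self, x: np.ndarray) -> np.ndarray:
        """Argmax class indices; exact ties resolve to 0 (HC)."""
        return np.argmax(self.forward(x), axis=1)

    def predict_labels(self, x: np.ndarray) -> list[str]:
        return [CLASSES[i] for i in self.predict_indices(x)]

    # -- training ----------------------------------------------------------
    def train_step(self, x: np.ndarray, y_onehot: np.ndarray) -> dict:
        """One gradient step; returns loss components for the batch."""
        h = self._check_batch(x)
        for layer in self.layers:
            h = layer.forward(h, training=True)
        bce, dz = _nn.bce_loss_and_grad(h, np.asarray(y_onehot, dtype=float))
        grad = self.layers[-1].backward(dz, preact=True)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        self.optimizer.step(self.layers)
        l1 = sum(layer.l1_penalty() for layer in self.layers)
        acc = float(np.mean(np.argmax(h, axis=1) == np.argmax(y_onehot, axis=1)))
        return {"loss": bce + l1, "bce": bce, "l1": l1, "accuracy": acc}

    def evaluate_loss(self, x: np.ndarray, y_onehot: np.ndarray) -> dict:
        p = self.forward(x)
        bce, _ = _nn.bce_loss_and_grad(p, np.asarray(y_onehot, dtype=float))
        l1 = sum(layer.l1_penalty() for layer in self.layers)
        acc = float(np.mean(np.argmax(p, axis=1) == np.argmax(y_onehot, axis=1)))
        return {"loss": bce + l1, "bce": bce, "l1": l1, "accuracy": acc}

    # -- audit / persistence ------------------------------------------------
    def summary(self) -> list[dict]:
        """Layer-by-layer audit regenerated from the built network."""
        rows = []
        for layer, ls in zip(self.layers, self.spec.layers):
            row = {"kind": ls.kind}
            if isinstance(layer, _nn.Conv2D):
                row.update(filters=layer.filters, kernel=layer.kernel,
                           stride=layer.stride, activation=layer.activation,
                           regularizer_l1=layer.l1)
            elif isinstance(layer, _nn.MaxPool2D):
                row.update(pool_size=layer.pool, stride=layer.stride)
            elif isinstance(layer, _nn.Dropout):
                row.update(rate=layer.rate)
            elif isinstance(layer, _nn.Dense):
                row.update(units=layer.units, activation=layer.activation,
                           regularizer_l1=layer.l1)
            rows.append(row)
        return rows

    def n_layers(self) -> int:
        return len(self.layers)

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params.values())
        return out

    def checksum(self) -> int:
        crc = 0
        for p in self.parameters():
            crc = zlib.crc32(np.ascontiguousarray(p).tobytes(), crc)
        return crc

    def save_weights(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = Path(str(path)).with_suffix(".json")
        sidecar.write_text(json.dumps({
            "spec": json.loads(self.spec.to_json()),
            "hyperparams": asdict(self.hp),
            "seed": self.seed,
        }, indent=1))

    def load_weights(self, path: str | Path) -> None:
        data = np.load(path)
        for i, p in enumerate(self.parameters()):
            p[...] = data[f"p{i}"]


def build_model(spec: ModelSpec, hp: Hyperparams = Hyperparams(), seed: int = 0) -> CNNModel:
    """Instantiate the network with seeded initialization and Adam attached."""
    return CNNModel(spec, hp, seed)
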