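"""Model construction: W-Net, its SVM-head variant, and the LSTM baseline.

W-Net is a shallow CNN for 128 x 128 x 3 inputs: three 3x3/stride-1
same-padded convolutions (16, 32, 64 filters), each followed by ReLU, a
2x2/stride-2 valid max-pool and dropout (p = 0.6); the 16 x 16 x 64 output
is flattened into a 1024-unit dense layer (ReLU + dropout) and a final
5-way dense layer.  With biases everywhere this gives exactly 16,806,949
trainable parameters (448 + 4,640 + 18,496 + 16,778,240 + 5,125).  Weights
use Xavier-uniform initialization, biases start at zero.

The softmax and SVM heads share the identical architecture and parameter
count; they differ only in the loss used during training (cross-entropy vs
one-vs-all hinge) and in whether ``forward`` maps scores through softmax.

The LSTM baseline reads each image as 128 timesteps (rows) of 384 features
(128 columns x 3 channels, channel-fastest within a row) through a single
32-unit LSTM and a 5-way softmax head.

Checkpoints are .npz files holding the named parameter arrays plus a hash
of the serialized architecture spec, so loading into a mismatched
architecture fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nnops
from .nnops import (Conv2D, Dense, Dropout, Flatten, MaxPool2x2, ReLU,
                    Sequential, LSTM, xavier_uniform_bound)

__all__ = ["LayerSpec", "ArchitectureSpec", "BuiltModel", "wnet_spec",
           "build_wnet", "build_from_spec", "build_lstm_baseline",
           "count_trainable_parameters", "xavier_uniform_bounds",
           "save_checkpoint", "load_checkpoint"]

NUM_CLASSES = 5
INPUT_SHAPE = (128, 128, 3)


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer description from which layers are instantiated."""

    kind: str  # conv | maxpool | flatten | dense | dropout | activation | lstm
    kernel: tuple[int, int] | None = None
    stride: int = 1
    filters: int | None = None  # conv filters or dense/lstm units
    padding: str = "same"
    activation: str | None = None  # for kind == 'activation': relu
    dropout_p: float | None = None

    def __post_init__(self):
        if self.kind == "conv" and (self.kernel is None
                                    or min(self.kernel) < 1):
            raise ValueError("conv layers need a positive kernel")
        if self.kind == "dropout" and not 0.0 <= (self.dropout_p or 0) < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Input shape, ordered layers, class count and classifier head."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    num_classes: int = NUM_CLASSES
    head: str = "softmax"  # softmax | svm

    def __post_init__(self):
        if self.head not in ("softmax", "svm"):
            raise ValueError("head must be 'softmax' or 'svm'")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def wnet_spec(head: str = "softmax", dropout_p: float = 0.6) -> ArchitectureSpec:
    """The canonical W-Net architecture spec."""
    layers = []
    for filters in (16, 32, 64):
        layers += [
            LayerSpec("conv", kernel=(3, 3), stride=1, filters=filters,
                      padding="same"),
            LayerSpec("activation", activation="relu"),
            LayerSpec("maxpool", kernel=(2, 2), stride=2, padding="valid"),
            LayerSpec("dropout", dropout_p=dropout_p),
        ]
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", filters=1024),
        LayerSpec("activation", activation="relu"),
        LayerSpec("dropout", dropout_p=dropout_p),
        LayerSpec("dense", filters=NUM_CLASSES),
    ]
    return ArchitectureSpec(tuple(layers), head=head)


class BuiltModel:
    """A runnable model: spec + named parameter arrays + forward pass.

    ``forward`` returns class probabilities for a softmax head and raw
    margin scores for an SVM head; ``forward_logits`` always returns the
    pre-head scores.  Dropout is active only when ``train=True`` and an rng
    is supplied.
    """

    def __init__(self, spec: ArchitectureSpec, net: Sequential,
                 input_rank: int = 4):
        self.spec = spec
        self.net = net
        self.input_rank = input_rank

    # -- inference ---------------------------------------------------------
    def forward_logits(self, x, train: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != self.input_rank:
            raise ValueError(
                f"expected a batch of rank {self.input_rank}, got shape {x.shape}")
        return self.net.forward(x, train=train, rng=rng)

    def forward(self, x, train: bool = False, rng=None) -> np.ndarray:
        logits = self.forward_logits(x, train=train, rng=rng)
        if self.spec.head == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return logits

    def predict(self, x) -> np.ndarray:
        return self.forward_logits(x).argmax(axis=1)

    # -- bookkeeping -------------------------------------------------------
    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return dict(self.net.named_parameters())

    @property
    def trainable_parameter_count(self) -> int:
        return self.net.parameter_count()


def count_trainable_parameters(model: BuiltModel) -> int:
    """Exact total element count over all weight and bias arrays."""
    return int(sum(p.size for p in model.parameters.values()))


def xavier_uniform_bounds(fan_in: int, fan_out: int) -> float:
    """Xavier-uniform bound x = sqrt(6/(fan_in + fan_out)); draws are U[-x, x]."""
    return xavier_uniform_bound(fan_in, fan_out)


def build_from_spec(spec: ArchitectureSpec, seed: int = 0) -> BuiltModel:
    """Instantiate a BuiltModel from a declarative spec."""
    rng_seeds = iter(np.random.SeedSequence(seed).generate_state(64) & 0x7FFFFFFF)
    h, w, c = spec.input_shape
    flat = None
    layers: list[nnops.Layer] = []
    for ls in spec.layers:
        if ls.kind == "conv":
            layers.append(Conv2D(c, ls.filters, kernel=ls.kernel[0],
                                 stride=ls.stride, padding=ls.padding,
                                 seed=int(next(rng_seeds))))
            c = ls.filters
            if ls.padding == "valid":
                h = (h - ls.kernel[0]) // ls.stride + 1
                w = (w - ls.kernel[1]) // ls.stride + 1
            else:
                h = -(-h // ls.stride)
                w = -(-w // ls.stride)
        elif ls.kind == "maxpool":
            layers.append(MaxPool2x2())
            h, w = h // 2, w // 2
        elif ls.kind == "activation":
            if ls.activation != "relu":
                raise ValueError(f"unsupported activation {ls.activation!r}")
            layers.append(ReLU())
        elif ls.kind == "dropout":
            layers.append(Dropout(ls.dropout_p))
        elif ls.kind == "flatten":
            layers.append(Flatten())
            flat = h * w * c
        elif ls.kind == "dense":
            if flat is None:
                raise ValueError("dense layer before flatten")
            layers.append(Dense(flat, ls.filters, seed=int(next(rng_seeds))))
            flat = ls.filters
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return BuiltModel(spec, Sequential(layers))


def build_wnet(head: str = "softmax", seed: int = 0,
               dropout_p: float = 0.6) -> BuiltModel:
    """Build W-Net (16,806,949 trainable parameters for either head)."""
    return build_from_spec(wnet_spec(head=head, dropout_p=dropout_p), seed=seed)


class _RowsAsSequences(nnops.Layer):
    """(N, 128, 128, 3) -> (N, 128, 384): rows are timesteps, features are the
    row's pixels flattened channel-fastest."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h, w * c)

    def backward(self, dout):
        return dout.reshape(self._shape)


def build_lstm_baseline(hidden_units: int = 32, seed: int = 0) -> BuiltModel:
    """Single-layer LSTM over image rows with a 5-way softmax head.

    A 128 x 128 x 3 image is consumed as 128 timesteps of 384 features.
    """
    ss = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    h, w, c = INPUT_SHAPE
    net = Sequential([
        _RowsAsSequences(),
        LSTM(w * c, hidden_units, seed=int(ss[0])),
        Dense(hidden_units, NUM_CLASSES, seed=int(ss[1])),
    ])
    spec = ArchitectureSpec(
        (LayerSpec("lstm", filters=hidden_units),
         LayerSpec("dense", filters=NUM_CLASSES)),
        head="softmax")
    return BuiltModel(spec, net)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: BuiltModel, path) -> None:
    """Write named parameter arrays plus the architecture-spec hash (.npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.net.get_state()
    np.savez(path, __spec_hash__=np.frombuffer(
        model.spec.hash().encode(), dtype=np.uint8), **state)


def load_checkpoint(model: BuiltModel, path) -> BuiltModel:
    """Load a checkpoint into a freshly built model of the same architecture."""
    with np.load(Path(path)) as data:
        stored = bytes(data["__spec_hash__"]).decode()
        if stored != model.spec.hash():
            raise ValueError(
                f"incompatible checkpoint: spec hash {stored} != "
                f"{model.spec.hash()}")
        model.net.set_state({k: data[k] for k in data.files
                             if k != "__spec_hash__"})
    return model
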