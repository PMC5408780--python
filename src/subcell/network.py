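"""Declarative construction of the localization classifier.

The architecture is a stack of 3x3 same-padding convolution blocks
(conv -> bias -> [batch norm] -> ReLU) with ceil-mode 2x2/2 max pooling after
configured blocks, followed by fully connected blocks and a final affine layer
whose softmax output is the distribution over localization classes. With the
default configuration (eight conv blocks of 64, 64, 128, 128, 256, 256, 256,
256 feature maps, pooling after blocks 2/4/8, FC widths 512/512, 19 output
classes, two input channels, 60x60 training input) the spatial trace is
60 -> 30 -> 15 -> 8 and the network holds over ten million trainable
parameters.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._layers import (
    Adam,
    BatchNorm,
    Conv2d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool2x2,
    ReLU,
    softmax,
)

__all__ = ["ModelConfig", "Network", "build_network", "count_parameters",
           "save_checkpoint", "load_checkpoint", "ConfigError"]

DEFAULT_CONV_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 256)


class ConfigError(ValueError):
    """Raised for inconsistent or invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description; defaults follow the published network."""

    input_size: int = 60
    in_channels: int = 2
    conv_widths: tuple[int, ...] = DEFAULT_CONV_WIDTHS
    pool_after: frozenset[int] = frozenset({2, 4, 8})
    fc_widths: tuple[int, ...] = (512, 512)
    n_classes: int = 19
    batch_norm: bool = True
    init_sd: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "conv_widths", tuple(self.conv_widths))
        object.__setattr__(self, "fc_widths", tuple(self.fc_widths))
        object.__setattr__(self, "pool_after", frozenset(self.pool_after))
        self.validate()

    def validate(self) -> None:
        if self.input_size < 1 or self.in_channels < 1:
            raise ConfigError("input_size and in_channels must be positive")
        if any(w <= 0 for w in self.conv_widths):
            raise ConfigError("conv widths must be positive")
        if any(w <= 0 for w in self.fc_widths):
            raise ConfigError("fc widths must be positive")
        if not self.pool_after <= set(range(1, len(self.conv_widths) + 1)):
            raise ConfigError("pool_after indices must reference existing conv layers")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if self.init_sd <= 0:
            raise ConfigError("init_sd must be positive")

    def spatial_trace(self) -> list[int]:
        """Spatial side length after each conv block (ceil-mode pooling)."""
        s, trace = self.input_size, []
        for i in range(1, len(self.conv_widths) + 1):
            if i in self.pool_after:
                s = math.ceil(s / 2)
            trace.append(s)
        return trace

    def flatten_length(self) -> int:
        if not self.conv_widths:
            return self.in_channels * self.input_size ** 2
        return self.conv_widths[-1] * self.spatial_trace()[-1] ** 2

    def to_json(self) -> str:
        d = asdict(self)
        d["pool_after"] = sorted(self.pool_after)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["conv_widths"] = tuple(d["conv_widths"])
        d["fc_widths"] = tuple(d["fc_widths"])
        d["pool_after"] = frozenset(d["pool_after"])
        return cls(**d)


class Network:
    """Realized classifier: named layer stack + forward/backward machinery."""

    def __init__(self, config: ModelConfig, layers: list[tuple[str, Layer]]):
        self.config = config
        self.layers = layers  # list of (name, layer)
        self._dropout: Dropout | None = None

    # -- construction helpers -------------------------------------------------

    def layer(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def parameter_layers(self) -> list[Layer]:
        return [l for _, l in self.layers if l.params]

    def set_final_dropout(self, rate: float, rng: np.random.Generator) -> None:
        """Insert (or replace) dropout immediately before the output layer."""
        self.layers = [(n, l) for n, l in self.layers if n != "dropout"]
        if rate > 0:
            self._dropout = Dropout(rate, rng)
            out_idx = next(i for i, (n, _) in enumerate(self.layers) if n == "out")
            self.layers.insert(out_idx, ("dropout", self._dropout))

    # -- forward / backward ---------------------------------------------------

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels \
                or x.shape[2] != x.shape[3]:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, S, S) input, got {x.shape}")
        h = np.asarray(x, dtype=np.float32)
        for _, layer in self.layers:
            h = layer.forward(h, training=training)
        return h

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probability vectors, one row per input crop."""
        return softmax(self.logits(x, training=training))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate from the output layer; returns d(input)."""
        d = dlogits
        for _, layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def extract_activations(self, x: np.ndarray, layer: str):
        """Post-ReLU activations at a named hidden layer.

        ``conv<i>`` returns ``(spatial maps (N, C, H, W), spatial-max-reduced
        (N, C))``; ``fc<i>`` returns the (N, width) feature matrix.
        """
        names = [n for n, _ in self.layers]
        relu_name = f"{layer}_relu"
        if relu_name not in names:
            raise KeyError(f"unknown layer {layer!r}; known: "
                           f"{sorted(n[:-5] for n in names if n.endswith('_relu'))}")
        h = np.asarray(x, dtype=np.float32)
        for n, lay in self.layers:
            h = lay.forward(h, training=False)
            if n == relu_name:
                if h.ndim == 4:
                    return h, h.max(axis=(2, 3))
                return h
        raise AssertionError("unreachable")

    def input_gradient(self, x: np.ndarray, target: tuple[str, int]):
        """Gradient of a scalar target w.r.t. the input pixels (eval mode).

        ``target=("out", k)`` uses the class-k logit summed over the batch;
        ``target=("conv<i>", f)`` uses the mean activation of feature map f.
        Returns ``(gradient, score)``.
        """
        layer_name, idx = target
        names = [n for n, _ in self.layers]
        stop = "out" if layer_name == "out" else f"{layer_name}_relu"
        if stop not in names:
            raise KeyError(f"target layer {layer_name!r} not in network")
        h = np.asarray(x, dtype=np.float32)
        upto = names.index(stop)
        for n, lay in self.layers[:upto + 1]:
            h = lay.forward(h, training=False)
        if idx >= h.shape[1]:
            raise IndexError(f"feature index {idx} out of range for {layer_name}")
        d = np.zeros_like(h)
        if h.ndim == 4:
            score = float(h[:, idx].mean())
            d[:, idx] = 1.0 / (h.shape[0] * h.shape[2] * h.shape[3])
        else:
            score = float(h[:, idx].sum())
            d[:, idx] = 1.0
        for _, lay in reversed(self.layers[:upto + 1]):
            d = lay.backward(d)
        return d, score

    # -- parameter bookkeeping ------------------------------------------------

    def count_parameters(self) -> int:
        return sum(l.n_parameters() for l in self.parameter_layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layer in self.layers:
            for k, v in layer.params.items():
                state[f"{name}.{k}"] = v
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for k in layer.params:
                layer.params[k] = state[f"{name}.{k}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{name}.running_mean"].copy()
                layer.running_var = state[f"{name}.running_var"].copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}

    def clone(self) -> "Network":
        return copy.deepcopy(self)


def build_network(config: ModelConfig, seed: int) -> Network:
    """Instantiate the architecture with truncated-normal(0, init_sd^2) weights.

    Weights are truncated at two standard deviations; biases start at zero,
    batch-norm scale/offset at one/zero. Deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, Layer]] = []
    c_in = config.in_channels
    for i, width in enumerate(config.conv_widths, start=1):
        layers.append((f"conv{i}", Conv2d(c_in, width, 3, config.init_sd, rng)))
        if config.batch_norm:
            layers.append((f"conv{i}_bn", BatchNorm(width)))
        layers.append((f"conv{i}_relu", ReLU()))
        if i in config.pool_after:
            layers.append((f"pool{i}", MaxPool2x2()))
        c_in = width
    layers.append(("flatten", Flatten()))
    n_in = config.flatten_length()
    for j, width in enumerate(config.fc_widths, start=1):
        layers.append((f"fc{j}", Linear(n_in, width, config.init_sd, rng)))
        if config.batch_norm:
            layers.append((f"fc{j}_bn", BatchNorm(width)))
        layers.append((f"fc{j}_relu", ReLU()))
        n_in = width
    layers.append(("out", Linear(n_in, config.n_classes, config.init_sd, rng)))
    return Network(config, layers)


def count_parameters(network: Network) -> int:
    """Exact count of trainable scalars (conv/FC weights+biases, BN scale/offset)."""
    return network.count_parameters()


def make_optimizer(network: Network) -> Adam:
    return Adam([l for _, l in network.layers])


def save_checkpoint(network: Network, path: str | Path) -> None:
    """Write config JSON + named weight arrays to an .npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=np.frombuffer(
        network.config.to_json().encode(), dtype=np.uint8), **network.state_dict())


def load_checkpoint(path: str | Path, config: ModelConfig | None = None) -> Network:
    """Rebuild a network from a checkpoint; verifies config if one is given."""
    with np.load(Path(path)) as data:
        cfg_json = bytes(data["__config__"]).decode()
        stored = ModelConfig.from_json(cfg_json)
        if config is not None and config != stored:
            raise ConfigError("checkpoint config does not match the requested config")
        net = build_network(stored, seed=0)
        net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net
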