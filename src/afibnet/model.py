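"""Declarative construction of the AF-detection 1D-CNN.

The full architecture takes a 2700-sample episode through 13 valid
convolutions (kernel 3 x 1, stride 1) interleaved with 5 max-pooling
layers (2 x 1, stride 2), reducing 2700 input nodes to 78 per feature
map; the 78 x 512 = 39,936-wide flatten feeds two 1000-unit dense
layers and a class head (1 sigmoid unit for N-vs-AF, 3 softmax units
for N/AF/Non-AF).  Hidden activations are ReLU; every layer carries
biases, giving 45,846,329 trainable parameters in the binary
configuration.

The architecture description (:class:`ModelConfig` / :class:`LayerSpec`)
is pure data: shape tracing and parameter accounting are closed-form
arithmetic over it and never allocate weights.  :func:`build_model`
instantiates the actual numpy network with seeded initialization.

A reduced configuration (:meth:`ModelConfig.scaled`) with the same
layer vocabulary but two convolution blocks and a small dense head
exists for CPU-scale experiments on synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .records import EPISODE_LENGTH, LABEL_AF, LABEL_N, LABEL_NON_AF

__all__ = [
    "LayerSpec", "ModelConfig", "TraceRow", "shape_trace",
    "count_parameters", "build_model", "AFibNetModel",
    "save_checkpoint", "load_checkpoint", "format_trace",
]

CONV_KERNEL = 3
POOL_SIZE = 2


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network template.

    Conv layers are fixed at kernel 3, stride 1, no padding (valid);
    pools at size 2, stride 2.  ``units`` applies to dense/output.
    """

    kind: str  # conv | maxpool | flatten | dense | output
    filters: int = 0
    kernel: int = CONV_KERNEL
    stride: int = 1
    units: int = 0
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "maxpool", "flatten", "dense", "output"):
            raise ValueError(f"unknown layer kind {self.kind!r}")


def _conv(filters: int) -> LayerSpec:
    return LayerSpec("conv", filters=filters, kernel=CONV_KERNEL, stride=1, activation="relu")


def _pool() -> LayerSpec:
    return LayerSpec("maxpool", kernel=POOL_SIZE, stride=POOL_SIZE)


def _afibnet_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    blocks = [
        [_conv(64), _conv(64)],
        [_conv(128), _conv(128)],
        [_conv(256), _conv(256), _conv(256)],
        [_conv(512), _conv(512), _conv(512)],
        [_conv(512), _conv(512), _conv(512)],
    ]
    layers: list[LayerSpec] = []
    for block in blocks:
        layers.extend(block)
        layers.append(_pool())
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", units=1000, activation="relu"))
    layers.append(LayerSpec("dense", units=1000, activation="relu"))
    if n_classes == 2:
        layers.append(LayerSpec("output", units=1, activation="sigmoid"))
    else:
        layers.append(LayerSpec("output", units=3, activation="softmax"))
    return tuple(layers)


def _scaled_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    # Two convolution blocks; the second block pools repeatedly so the
    # dense head sees few positions (168), which lets the rhythm cues be
    # read out position-invariantly within a short optimization budget.
    layers = [
        _conv(16), _pool(),
        _conv(32), _pool(), _pool(), _pool(),
        LayerSpec("flatten"),
        LayerSpec("dense", units=512, activation="relu"),
        LayerSpec("dense", units=64, activation="relu"),
    ]
    if n_classes == 2:
        layers.append(LayerSpec("output", units=1, activation="sigmoid"))
    else:
        layers.append(LayerSpec("output", units=3, activation="softmax"))
    return tuple(layers)


@dataclass
class ModelConfig:
    """Network template plus input contract.

    ``n_classes`` selects the head: 2 -> one sigmoid unit (AF as the
    positive class), 3 -> three softmax units over (N, AF, NON_AF).
    """

    layers: tuple[LayerSpec, ...] = ()
    n_classes: int = 2
    input_length: int = EPISODE_LENGTH
    input_channels: int = 1
    name: str = "afibnet"

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if not self.layers:
            self.layers = _afibnet_layers(self.n_classes)
        self.validate()

    @classmethod
    def afibnet(cls, n_classes: int = 2) -> "ModelConfig":
        """The full 13-convolution / 5-pool architecture."""
        return cls(layers=_afibnet_layers(n_classes), n_classes=n_classes, name="afibnet")

    @classmethod
    def scaled(cls, n_classes: int = 2) -> "ModelConfig":
        """A two-block reduction for CPU-scale synthetic experiments."""
        return cls(layers=_scaled_layers(n_classes), n_classes=n_classes, name="afibnet-scaled")

    @property
    def classes(self) -> tuple[str, ...]:
        return (LABEL_N, LABEL_AF) if self.n_classes == 2 else (LABEL_N, LABEL_AF, LABEL_NON_AF)

    def validate(self) -> None:
        """Reject any deviation from the layer template, naming the
        first offending layer."""
        for i, spec in enumerate(self.layers):
            where = f"layer {i} ({spec.kind})"
            if spec.kind == "conv":
                if spec.kernel != CONV_KERNEL or spec.stride != 1:
                    raise ValueError(
                        f"{where}: conv layers must use kernel {CONV_KERNEL}, stride 1, "
                        f"got kernel {spec.kernel}, stride {spec.stride}"
                    )
                if spec.filters < 1:
                    raise ValueError(f"{where}: conv layer needs a positive filter count")
            elif spec.kind == "maxpool":
                if spec.kernel != POOL_SIZE or spec.stride != POOL_SIZE:
                    raise ValueError(
                        f"{where}: pool layers must use size {POOL_SIZE}, stride {POOL_SIZE}"
                    )
            elif spec.kind in ("dense", "output") and spec.units < 1:
                raise ValueError(f"{where}: needs a positive unit count")
        out = self.layers[-1]
        if out.kind != "output":
            raise ValueError("last layer must be the output head")
        expected_units = 1 if self.n_classes == 2 else 3
        if out.units != expected_units:
            raise ValueError(
                f"output head must have {expected_units} unit(s) for "
                f"{self.n_classes} classes, got {out.units}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_classes": self.n_classes,
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "layers": [vars(s) | {} for s in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        layers = tuple(LayerSpec(**spec) for spec in d["layers"])
        return cls(layers=layers, n_classes=d["n_classes"],
                   input_length=d["input_length"],
                   input_channels=d["input_channels"], name=d.get("name", "afibnet"))


@dataclass(frozen=True)
class TraceRow:
    """One line of the architecture trace: output shape and trainable
    parameter count of a layer."""

    name: str
    output_length: int
    output_channels: int
    parameters: int


def shape_trace(config: ModelConfig) -> list[TraceRow]:
    """Closed-form per-layer output shapes and parameter counts.

    Conv: L -> L - 2, params = (kernel * in_ch + 1) * filters.
    Pool: L -> L // 2, no params.  Dense/output: (fan_in + 1) * units.
    Flat layers report output_channels = 1.
    """
    rows: list[TraceRow] = []
    length, channels = config.input_length, config.input_channels
    counters = {"conv": 0, "maxpool": 0, "dense": 0}
    flat: int | None = None
    for spec in config.layers:
        if spec.kind == "conv":
            counters["conv"] += 1
            length = length - spec.kernel + 1
            params = (spec.kernel * channels + 1) * spec.filters
            channels = spec.filters
            rows.append(TraceRow(f"conv{counters['conv']}", length, channels, params))
        elif spec.kind == "maxpool":
            counters["maxpool"] += 1
            length = length // POOL_SIZE
            rows.append(TraceRow(f"maxpool{counters['maxpool']}", length, channels, 0))
        elif spec.kind == "flatten":
            flat = length * channels
            rows.append(TraceRow("flatten", flat, 1, 0))
        elif spec.kind == "dense":
            counters["dense"] += 1
            fan_in = flat if flat is not None else length * channels
            params = (fan_in + 1) * spec.units
            flat = spec.units
            rows.append(TraceRow(f"dense{counters['dense']}", spec.units, 1, params))
        else:  # output
            fan_in = flat if flat is not None else length * channels
            params = (fan_in + 1) * spec.units
            rows.append(TraceRow("output", spec.units, 1, params))
    return rows


class AFibNetModel:
    """A built network: config + seeded numpy weights + prediction contract."""

    def __init__(self, config: ModelConfig, seed: int = 0, network: _nn.Sequential | None = None):
        self.config = config
        self.seed = int(seed)
        self.network = network if network is not None else self._build_network()

    def _build_network(self) -> _nn.Sequential:
        rng = np.random.Generator(np.random.Philox(key=self.seed))
        layers: list[_nn.Layer] = []
        length, channels = self.config.input_length, self.config.input_channels
        flat = None
        for spec in self.config.layers:
            if spec.kind == "conv":
                layers.append(_nn.Conv1D(channels, spec.filters, spec.kernel, rng))
                layers.append(_nn.ReLU())
                length, channels = length - spec.kernel + 1, spec.filters
            elif spec.kind == "maxpool":
                layers.append(_nn.MaxPool1D())
                length //= POOL_SIZE
            elif spec.kind == "flatten":
                layers.append(_nn.Flatten())
                flat = length * channels
            elif spec.kind == "dense":
                layers.append(_nn.Dense(flat, spec.units, rng))
                layers.append(_nn.ReLU())
                flat = spec.units
            else:
                layers.append(_nn.Dense(flat, spec.units, rng))
        return _nn.Sequential(layers)

    # -- introspection ----------------------------------------------------

    def shape_trace(self) -> list[TraceRow]:
        return shape_trace(self.config)

    def count_parameters(self) -> int:
        return count_parameters(self.config)

    # -- prediction -------------------------------------------------------

    def forward_logits(self, values: np.ndarray) -> np.ndarray:
        x = _check_lengths(values, self.config.input_length)
        return self.network.forward(x[:, :, None].astype(np.float32))

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Per-episode class probabilities, columns ordered as
        ``config.classes``; rows sum to 1."""
        values = _check_lengths(values, self.config.input_length)
        logits = self.network.forward(values[:, :, None].astype(np.float32))
        if self.config.n_classes == 2:
            p_af = _nn._sigmoid(logits.reshape(-1))
            return np.column_stack([1.0 - p_af, p_af])
        return _nn._softmax(logits)

    def predict(self, values: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Probabilities and hard labels.

        Binary: label AF iff p(AF) >= 0.5 (ties break toward the
        positive class).  Three-class: argmax, first-max tie-break.
        """
        proba = self.predict_proba(values)
        classes = self.config.classes
        if self.config.n_classes == 2:
            labels = [classes[1] if p >= 0.5 else classes[0] for p in proba[:, 1]]
        else:
            labels = [classes[i] for i in proba.argmax(axis=1)]
        return proba, labels


def _check_lengths(values, expected: int) -> np.ndarray:
    """Stack episode values into a (batch, length) array, rejecting any
    episode of the wrong length by index."""
    if isinstance(values, (list, tuple)):
        for i, v in enumerate(values):
            if len(np.atleast_1d(v)) != expected:
                raise ValueError(
                    f"episode {i} has length {len(np.atleast_1d(v))}, expected {expected}"
                )
        values = np.stack([np.asarray(v, dtype=float) for v in values])
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != expected:
        raise ValueError(f"episode 0 has length {values.shape[1]}, expected {expected}")
    return values


def build_model(config: ModelConfig, seed: int = 0) -> AFibNetModel:
    """Instantiate the network with seeded weight initialization.

    The same (config, seed) pair always yields identical weights.
    """
    config.validate()
    return AFibNetModel(config, seed=seed)


def count_parameters(config_or_model) -> int:
    """Total trainable scalars (weights + biases in every layer)."""
    config = config_or_model.config if isinstance(config_or_model, AFibNetModel) else config_or_model
    return int(sum(row.parameters for row in shape_trace(config)))


def format_trace(config: ModelConfig) -> str:
    """Render the architecture trace as an aligned text table."""
    rows = shape_trace(config)
    lines = [f"{'layer':<10} {'output shape':>14} {'parameters':>12}"]
    for r in rows:
        shape = f"{r.output_length}×{r.output_channels}" if r.output_channels > 1 else f"{r.output_length}"
        lines.append(f"{r.name:<10} {shape:>14} {r.parameters:>12,}")
    lines.append(f"{'total':<10} {'':>14} {count_parameters(config):>12,}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Checkpoints: single .npz holding config JSON, seed, and every weight array.
# ---------------------------------------------------------------------------

def save_checkpoint(model: AFibNetModel, path) -> None:
    from . import __version__

    arrays = {f"param_{i}": p for i, p in enumerate(model.network.params)}
    meta = json.dumps({
        "config": model.config.to_dict(),
        "seed": model.seed,
        "version": __version__,
    })
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> AFibNetModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        model = AFibNetModel(config, seed=meta["seed"])
        params = model.network.params
        for i, p in enumerate(params):
            loaded = data[f"param_{i}"]
            if loaded.shape != p.shape:
                raise ValueError(
                    f"checkpoint/config mismatch at parameter {i}: "
                    f"{loaded.shape} vs {p.shape} (checkpoint version {meta['version']})"
                )
            p[...] = loaded
    return model
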