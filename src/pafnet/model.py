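"""The residual-CNN + Transformer-encoder AF classifier.

Architecture: a conv/BN/ReLU stem, eight residual blocks (kernel 16,
filters 32 doubling at block 5, stride 2 in the even-numbered blocks, a
parameter-free max-pool shortcut with channel zero-padding at the width
change), a learned positional table added to the 38-step embedding, one
Transformer encoder layer (8 heads, embedding 64, feed-forward width 32),
global average pooling and a 64->32->1 sigmoid head.

``audit_parameters`` produces the exact per-layer and total parameter
counts of this construction; the reference totals are 653,505 parameters
of which 651,905 are trainable (the 1,600 non-trainable ones are the
batch-norm running statistics).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .postprocess import LabelSequence
from .records import ValidationError

__all__ = [
    "NetworkSpec",
    "ParamAudit",
    "AuditRow",
    "build_network",
    "audit_parameters",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    """Every hyperparameter needed to rebuild the classifier exactly."""

    input_length: int = 600
    kernel_size: int = 16
    n_blocks: int = 8
    filters_initial: int = 32
    filters_double_at_block: int = 5    # 1-based block index where width doubles
    d_model: int = 64
    n_heads: int = 8
    ffn_hidden: int = 32
    pos_table_len: int = 50
    n_encoder_layers: int = 1
    head_hidden: int = 32
    dropout_rate: float = 0.2

    def validate(self) -> None:
        if self.d_model % self.n_heads:
            raise ValidationError("d_model must be divisible by n_heads")
        if self.final_channels != self.d_model:
            raise ValidationError(
                f"residual stack ends at {self.final_channels} channels but "
                f"the encoder expects d_model={self.d_model}")
        if self.pos_table_len < self.encoder_length:
            raise ValidationError("positional table shorter than the sequence")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")

    def block_stride(self, block: int) -> int:
        """Subsample stride of 1-based block index: 1 if odd, 2 if even."""
        return 1 if block % 2 else 2

    def block_channels(self, block: int) -> int:
        return (self.filters_initial * 2
                if block >= self.filters_double_at_block else self.filters_initial)

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def final_channels(self) -> int:
        return self.block_channels(self.n_blocks)

    @property
    def encoder_length(self) -> int:
        """Temporal length entering the encoder (ceil division per stride-2)."""
        length = self.input_length
        for b in range(1, self.n_blocks + 1):
            length = -(-length // self.block_stride(b))
        return length


@dataclass
class AuditRow:
    name: str
    output_shape: tuple
    params: int
    trainable: int


@dataclass
class ParamAudit:
    """Per-layer parameter accounting of a built network."""

    per_layer: list[AuditRow] = field(default_factory=list)
    total: int = 0
    trainable: int = 0

    @property
    def non_trainable(self) -> int:
        return self.total - self.trainable

    def count(self, name: str) -> int:
        """Parameter count of the row whose name matches exactly."""
        for row in self.per_layer:
            if row.name == name:
                return row.params
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps({
            "per_layer": [asdict(r) for r in self.per_layer],
            "total": self.total,
            "trainable": self.trainable,
            "non_trainable": self.non_trainable,
        }, indent=2)


def build_network(spec: NetworkSpec, seed: int = 0,
                  dtype=np.float32) -> nn.Network:
    """Assemble the network; weight init and dropout draw from ``seed``."""
    spec.validate()
    ss = np.random.SeedSequence(seed)
    rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    layers: list[nn.Layer] = [
        nn.Conv1D(1, spec.filters_initial, spec.kernel_size, 1, rng,
                  "stem.conv", dtype),
        nn.BatchNorm(spec.filters_initial, name="stem.bn", dtype=dtype),
        nn.ReLU(),
    ]
    c_in = spec.filters_initial
    for b in range(1, spec.n_blocks + 1):
        c_out = spec.block_channels(b)
        layers.append(nn.ResidualBlock(
            c_in, c_out, spec.kernel_size, spec.block_stride(b),
            spec.dropout_rate, rng, drop_rng, f"block{b}", dtype))
        c_in = c_out
    layers.append(nn.PositionalEmbedding(spec.pos_table_len, spec.d_model, rng,
                                         "position_encoding", dtype))
    for e in range(spec.n_encoder_layers):
        layers.append(nn.TransformerEncoderLayer(
            spec.d_model, spec.n_heads, spec.ffn_hidden, rng,
            f"encoder{e + 1}", dtype))
    layers += [
        nn.GlobalAveragePooling(),
        nn.Dense(spec.d_model, spec.head_hidden, rng, "head.dense1", dtype),
        nn.ReLU(),
        nn.Dropout(spec.dropout_rate, drop_rng),
        nn.Dense(spec.head_hidden, 1, rng, "head.dense2", dtype),
    ]
    net = nn.Network(layers, rng)
    net.spec = spec
    return net


def _layer_param_counts(layer: nn.Layer) -> tuple[int, int]:
    params = layer.params()
    total = sum(p.size for p in params)
    trainable = sum(p.size for p in params if p.trainable)
    return total, trainable


def audit_parameters(network: nn.Network) -> ParamAudit:
    """Exact integer parameter counts, per layer and in total.

    Residual blocks are reported per inner conv/BN; each encoder layer is
    one aggregated row (matching how framework summaries print custom
    layers).  Output shapes are traced with a single dummy forward pass.
    """
    spec: NetworkSpec = network.spec
    shapes = {}
    x = np.zeros((1, spec.input_length, 1), dtype=np.float32)
    for layer in network.layers:
        x = layer.forward(x, training=False)
        shapes[id(layer)] = tuple(x.shape[1:])

    audit = ParamAudit()

    def add(name: str, shape: tuple, layer: nn.Layer) -> None:
        total, trainable = _layer_param_counts(layer)
        audit.per_layer.append(AuditRow(name, shape, total, trainable))

    for layer in network.layers:
        shape = shapes[id(layer)]
        if isinstance(layer, nn.ResidualBlock):
            for sub in (layer.conv1, layer.bn1, layer.conv2, layer.bn2):
                add(sub.name, shape, sub)
        elif isinstance(layer, (nn.Conv1D, nn.BatchNorm, nn.PositionalEmbedding,
                                nn.TransformerEncoderLayer, nn.Dense)):
            add(layer.name, shape, layer)
        else:
            audit.per_layer.append(AuditRow(layer.name, shape, 0, 0))
    audit.total = sum(r.params for r in audit.per_layer)
    audit.trainable = sum(r.trainable for r in audit.per_layer)
    return audit


def predict_labels(network: nn.Network, samples, threshold: float = 0.5,
                   batch_size: int = 256) -> LabelSequence:
    """Per-sample AF labels (probability >= threshold) in input order."""
    samples = list(samples)
    if not samples:
        return LabelSequence(np.zeros(0, dtype=bool), np.zeros(0, dtype=np.int64))
    x = np.stack([s.values for s in samples]).astype(np.float32)[:, :, None]
    probs = network.predict_proba(x, batch_size).ravel()
    return LabelSequence(
        labels=probs >= threshold,
        start_beats=np.asarray([s.start_beat for s in samples], dtype=np.int64),
        record_id=samples[0].record_id,
        probabilities=probs,
        channel=samples[0].channel,
    )


def save_checkpoint(network: nn.Network, path) -> None:
    """Weights as .npz plus a framework-agnostic JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **network.state_dict())
    manifest = {
        "spec": asdict(network.spec),
        "audit": json.loads(audit_parameters(network).to_json()),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path, seed: int = 0) -> nn.Network:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(**manifest["spec"])
    network = build_network(spec, seed=seed)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        network.load_state_dict({k: data[k] for k in data.files})
    return network
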