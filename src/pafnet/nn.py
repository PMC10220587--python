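"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layer set needed by the AF classifier: 1-D
convolutions with "same" padding and stride, batch normalization,
ReLU, dropout, max-pool shortcuts, learned positional embeddings,
multi-head self-attention with layer normalization, a position-wise
feed-forward block, global average pooling and dense heads — each with
a hand-written backward pass — plus the RAdam optimizer.

Conventions: activations are ``(batch, length, channels)`` arrays;
dense layers act on the last axis.  A layer caches whatever its
backward pass needs during ``forward(training=True)``.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "MaxPoolShortcut",
    "ChannelZeroPad",
    "ResidualBlock",
    "PositionalEmbedding",
    "MultiHeadSelfAttention",
    "LayerNorm",
    "FeedForward",
    "TransformerEncoderLayer",
    "GlobalAveragePooling",
    "Dense",
    "Network",
    "RAdam",
    "sigmoid",
    "bce_with_logits",
    "bce_with_logits_grad",
]


class Param:
    """A named tensor with an accumulated gradient.

    ``trainable=False`` marks state that belongs to the model but is not
    updated by gradient descent (batch-norm running statistics).
    """

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    """Base class: stateless layers only need ``forward``/``backward``."""

    name = "layer"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# Convolutional stage
# ---------------------------------------------------------------------------


class Conv1D(Layer):
    """1-D convolution, "same" padding, output length ceil(L / stride).

    Weight layout is ``(kernel, c_in, c_out)``; the forward pass lowers the
    input to columns and runs one matmul.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv1d",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.name = name
        w = _glorot_uniform(rng, (kernel, c_in, c_out), kernel * c_in, c_out, dtype)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._cache = None
        # persistent scratch, reused across steps: repeated 100+ MB
        # malloc/free cycles otherwise dominate the runtime via page faults
        self._bufs: dict[tuple, list[np.ndarray]] = {}

    def _scratch(self, key: tuple, shapes: list[tuple], dtype) -> list[np.ndarray]:
        bufs = self._bufs.get(key)
        if bufs is None or bufs[0].dtype != dtype:
            bufs = [np.empty(s, dtype=dtype) for s in shapes]
            self._bufs = {key: bufs}
        return bufs

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad_amounts(self, length: int) -> tuple[int, int, int]:
        out = -(-length // self.stride)
        total = max((out - 1) * self.stride + self.kernel - length, 0)
        return out, total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, length, _ = x.shape
        out, pl, pr = self._pad_amounts(length)
        key = (b, length)
        cols4, gcols, gxp = self._scratch(key, [
            (b, out, self.kernel, self.c_in),
            (b * out, self.kernel * self.c_in),
            (b, length + pl + pr, self.c_in)], x.dtype)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (b, out, kernel, c_in) gather -> columns (b*out, kernel*c_in)
        win = sliding_window_view(xp, self.kernel, axis=1)[:, ::self.stride]
        np.copyto(cols4, np.swapaxes(win, 2, 3))
        cols = cols4.reshape(b * out, -1)
        wm = self.w.value.reshape(self.kernel * self.c_in, self.c_out)
        y = cols @ wm + self.b.value
        if training:
            self._cache = (b, length, out, pl, pr)
        return y.reshape(b, out, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, length, out, pl, pr = self._cache
        self._cache = None
        cols4, gcols_buf, gxp = self._bufs[(b, length)]
        cols = cols4.reshape(b * out, -1)
        g = grad.reshape(b * out, self.c_out)
        wm = self.w.value.reshape(self.kernel * self.c_in, self.c_out)
        self.w.grad += (cols.T @ g).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=0)
        gcols = np.matmul(g, wm.T, out=gcols_buf).reshape(b, out, self.kernel, self.c_in)
        gxp[...] = 0.0
        for k in range(self.kernel):
            gxp[:, k:k + self.stride * out:self.stride] += gcols[:, :, k]
        return gxp[:, pl:pl + length]


class BatchNorm(Layer):
    """Batch normalization over (batch, time) per channel.

    gamma/beta are trainable; running mean/variance are carried as
    non-trainable parameters so the audit counts 4 per channel.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "batch_norm", dtype=np.float32):
        self.name = name
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = Param(f"{name}.moving_mean",
                                  np.zeros(channels, dtype=dtype), trainable=False)
        self.running_var = Param(f"{name}.moving_var",
                                 np.ones(channels, dtype=dtype), trainable=False)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value
                                       + (1 - m) * mean).astype(x.dtype)
            self.running_var.value = (m * self.running_var.value
                                      + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean.value, self.running_var.value
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std, x.shape[0] * x.shape[1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, n = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        gy = grad * self.gamma.value
        mean_gy = gy.mean(axis=(0, 1))
        mean_gyx = (gy * xhat).mean(axis=(0, 1))
        return (gy - mean_gy - xhat * mean_gyx) / std


class ReLU(Layer):
    name = "relu"

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return grad * mask


class Dropout(Layer):
    """Inverted dropout; identity when ``rate == 0`` or at inference."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        mask, self._mask = self._mask, None
        return grad * mask


class MaxPoolShortcut(Layer):
    """Max pooling with pool size == stride and ceil output length.

    Used as the parameter-free residual shortcut; stride 1 is the identity.
    """

    name = "max_pool"

    def __init__(self, stride: int):
        self.stride = stride
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.stride
        if s == 1:
            return x
        b, length, c = x.shape
        out = -(-length // s)
        pad = out * s - length
        xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        xw = xp.reshape(b, out, s, c)
        arg = xw.argmax(axis=2)
        if training:
            self._cache = (arg, (b, length, c, out, pad))
        return np.take_along_axis(xw, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.stride == 1:
            return grad
        cache, self._cache = self._cache, None
        arg, (b, length, c, out, pad) = cache
        gxp = np.zeros((b, out, self.stride, c), dtype=grad.dtype)
        np.put_along_axis(gxp, arg[:, :, None, :], grad[:, :, None, :], axis=2)
        return gxp.reshape(b, out * self.stride, c)[:, :length]


class ChannelZeroPad(Layer):
    """Zero-pads the channel axis (parameter-free width expansion)."""

    name = "channel_pad"

    def __init__(self, extra: int):
        self.extra = extra

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.extra == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (0, self.extra)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.extra == 0:
            return grad
        return grad[:, :, :-self.extra]


class ResidualBlock(Layer):
    """conv -> BN -> ReLU -> dropout -> conv -> BN, max-pool shortcut, sum, ReLU.

    The first convolution carries the block's subsample stride; the shortcut
    max-pool matches it, and channel widening is done by zero-padding so the
    shortcut stays parameter-free.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 dropout_rate: float, rng: np.random.Generator,
                 drop_rng: np.random.Generator, name: str, dtype=np.float32):
        self.name = name
        self.conv1 = Conv1D(c_in, c_out, kernel, stride, rng, f"{name}.conv1", dtype)
        self.bn1 = BatchNorm(c_out, name=f"{name}.bn1", dtype=dtype)
        self.relu1 = ReLU()
        self.drop = Dropout(dropout_rate, drop_rng)
        self.conv2 = Conv1D(c_out, c_out, kernel, 1, rng, f"{name}.conv2", dtype)
        self.bn2 = BatchNorm(c_out, name=f"{name}.bn2", dtype=dtype)
        self.pool = MaxPoolShortcut(stride)
        self.pad = ChannelZeroPad(c_out - c_in)
        self.relu_out = ReLU()
        self._main = [self.conv1, self.bn1, self.relu1, self.drop,
                      self.conv2, self.bn2]

    def params(self) -> list[Param]:
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        main = x
        for layer in self._main:
            main = layer.forward(main, training)
        short = self.pad.forward(self.pool.forward(x, training), training)
        return self.relu_out.forward(main + short, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gshort = self.pool.backward(self.pad.backward(g))
        gmain = g
        for layer in reversed(self._main):
            gmain = layer.backward(gmain)
        return gmain + gshort


# ---------------------------------------------------------------------------
# Transformer encoder stage
# ---------------------------------------------------------------------------


class PositionalEmbedding(Layer):
    """Learned positional table added to the input, sliced to its length."""

    def __init__(self, table_len: int, d_model: int, rng: np.random.Generator,
                 name: str = "position_encoding", dtype=np.float32):
        self.name = name
        # zero init: positions start neutral and are learned from data
        self.table = Param(f"{name}.table", np.zeros((table_len, d_model), dtype=dtype))
        self._len = None

    def params(self) -> list[Param]:
        return [self.table]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        length = x.shape[1]
        if length > self.table.value.shape[0]:
            raise ValueError(
                f"sequence length {length} exceeds positional table "
                f"capacity {self.table.value.shape[0]}")
        self._len = length
        return x + self.table.value[:length]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.table.grad[:self._len] += grad.sum(axis=0)
        return grad


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str = "dense", dtype=np.float32):
        self.name = name
        self.d_in, self.d_out = d_in, d_out
        self.w = Param(f"{name}.w", _glorot_uniform(rng, (d_in, d_out), d_in, d_out, dtype))
        self.b = Param(f"{name}.b", np.zeros(d_out, dtype=dtype))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        x2 = x.reshape(-1, self.d_in)
        g2 = grad.reshape(-1, self.d_out)
        self.w.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return (g2 @ self.w.value.T).reshape(x.shape)


class LayerNorm(Layer):
    """Layer normalization over the feature axis."""

    def __init__(self, d: int, eps: float = 1e-5, name: str = "layer_norm",
                 dtype=np.float32):
        self.name = name
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(d, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(d, dtype=dtype))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.beta.grad += grad.sum(axis=tuple(range(grad.ndim - 1)))
        gy = grad * self.gamma.value
        mean_gy = gy.mean(axis=-1, keepdims=True)
        mean_gyx = (gy * xhat).mean(axis=-1, keepdims=True)
        return (gy - mean_gy - xhat * mean_gyx) / std


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with h heads.

    Q, K, V are linear projections of the same input; each head attends with
    softmax(Q K^T / sqrt(d_k)) V and the concatenated heads pass through an
    output projection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 name: str = "mha", dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.name = name
        self.d_model, self.h = d_model, n_heads
        self.d_k = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng, f"{name}.wq", dtype)
        self.wk = Dense(d_model, d_model, rng, f"{name}.wk", dtype)
        self.wv = Dense(d_model, d_model, rng, f"{name}.wv", dtype)
        self.wo = Dense(d_model, d_model, rng, f"{name}.wo", dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return (self.wq.params() + self.wk.params() + self.wv.params()
                + self.wo.params())

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, length, _ = x.shape
        return x.reshape(b, length, self.h, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, length, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, length, h * dk)

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Softmax attention matrices (batch, heads, L, L) — inspection only."""
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        return _softmax_last(q @ np.swapaxes(k, -1, -2) / math.sqrt(self.d_k))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        q = self._split(self.wq.forward(x, training))
        k = self._split(self.wk.forward(x, training))
        v = self._split(self.wv.forward(x, training))
        attn = _softmax_last(q @ np.swapaxes(k, -1, -2) / math.sqrt(self.d_k))
        ctx = self._merge(attn @ v)
        if training:
            self._cache = (q, k, v, attn)
        return self.wo.forward(ctx, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        self._cache = None
        gctx = self._split(self.wo.backward(grad))
        gattn = gctx @ np.swapaxes(v, -1, -2)
        gv = np.swapaxes(attn, -1, -2) @ gctx
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores /= math.sqrt(self.d_k)
        gq = gscores @ k
        gk = np.swapaxes(gscores, -1, -2) @ q
        return (self.wq.backward(self._merge(gq))
                + self.wk.backward(self._merge(gk))
                + self.wv.backward(self._merge(gv)))


class FeedForward(Layer):
    """Position-wise feed-forward: dense -> ReLU -> dense."""

    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator,
                 name: str = "ffn", dtype=np.float32):
        self.name = name
        self.fc1 = Dense(d_model, hidden, rng, f"{name}.fc1", dtype)
        self.relu = ReLU()
        self.fc2 = Dense(hidden, d_model, rng, f"{name}.fc2", dtype)

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.fc2.forward(
            self.relu.forward(self.fc1.forward(x, training), training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.fc2.backward(grad)))


class TransformerEncoderLayer(Layer):
    """Post-norm encoder layer: MHA + residual + LN, FFN + residual + LN."""

    def __init__(self, d_model: int, n_heads: int, ffn_hidden: int,
                 rng: np.random.Generator, name: str = "encoder", dtype=np.float32):
        self.name = name
        self.mha = MultiHeadSelfAttention(d_model, n_heads, rng, f"{name}.mha", dtype)
        self.ln1 = LayerNorm(d_model, name=f"{name}.ln1", dtype=dtype)
        self.ffn = FeedForward(d_model, ffn_hidden, rng, f"{name}.ffn", dtype)
        self.ln2 = LayerNorm(d_model, name=f"{name}.ln2", dtype=dtype)

    def params(self) -> list[Param]:
        return (self.mha.params() + self.ln1.params()
                + self.ffn.params() + self.ln2.params())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.ln1.forward(x + self.mha.forward(x, training), training)
        return self.ln2.forward(a + self.ffn.forward(a, training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.ln2.backward(grad)
        g = g + self.ffn.backward(g)
        g = self.ln1.backward(g)
        return g + self.mha.backward(g)


class GlobalAveragePooling(Layer):
    name = "global_average_pooling"

    def __init__(self):
        self._len = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._len, axis=1) / self._len


# ---------------------------------------------------------------------------
# Network container, loss, optimizer
# ---------------------------------------------------------------------------


class Network:
    """An ordered chain of layers ending in a single logit per sample."""

    def __init__(self, layers: Sequence[Layer], rng: np.random.Generator):
        self.layers = list(layers)
        self.rng = rng

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def trainable_params(self) -> list[Param]:
        return [p for p in self.params() if p.trainable]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid probabilities, evaluated in inference mode."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(sigmoid(self.forward(x[i:i + batch_size], training=False)))
        if not outs:
            return np.zeros((0, 1), dtype=np.float32)
        return np.concatenate(outs, axis=0)

    def release_scratch(self) -> None:
        """Free the convolution scratch buffers (kept for step-to-step reuse
        during training; a trained network does not need them retained)."""
        stack = list(self.layers)
        while stack:
            layer = stack.pop()
            if isinstance(layer, Conv1D):
                layer._bufs = {}
            elif isinstance(layer, ResidualBlock):
                stack.extend([layer.conv1, layer.conv2])

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from logits."""
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    # log(1 + e^z) = max(z, 0) + log1p(e^{-|z|})
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())

def bce_with_logits_grad(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits)."""
    p = sigmoid(logits)
    return ((p - targets.reshape(p.shape)) / logits.size).astype(logits.dtype)


class RAdam:
    """Rectified Adam: Adam with variance-rectified adaptive learning rate.

    Falls back to an un-adapted momentum update while the variance estimate
    is untrustworthy (rectification term rho_t <= 4).
    """

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        if rho_t > 4.0:
            r = math.sqrt(((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                          / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t))
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1.0 - b1 ** t)
            if r is not None:
                vhat = np.sqrt(v / (1.0 - b2 ** t))
                update = self.lr * r * mhat / (vhat + self.eps)
            else:
                update = self.lr * mhat
            p.value[...] = (p.value - update).astype(p.value.dtype)
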