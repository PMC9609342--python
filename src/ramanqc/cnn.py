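"""A small, dependency-free 1-D convolutional regression network.

Implements exactly the layer stack used for spectral calibration here —
valid-padding stride-1 convolutions, ReLU, batch normalisation, stride-1
max pooling, dense layers — with mean-squared-error loss, the Adam
optimizer and train-loss early stopping.  Everything is plain numpy
(float32, single threaded), so training is deterministic for a fixed seed.

Data layout is channels-last: activations have shape
``(batch, length, filters)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ArchitectureError, ParameterError, TrainingError

EPS = 1e-5


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_length(self, length: int) -> int:
        return length


class Conv1D(_Layer):
    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        fan_in = in_ch * kernel
        self.kernel = kernel
        self.W = (rng.standard_normal((kernel * in_ch, filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_length(self, length: int) -> int:
        return length - self.kernel + 1

    def forward(self, x, train):
        # x: (B, L, C) -> cols: (B, L', k*C)
        win = sliding_window_view(x, self.kernel, axis=1)  # (B, L', C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(x.shape[0], -1,
                                                 self.kernel * x.shape[2])
        self._cols = cols if train else None
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, dy):
        B, Lp, F = dy.shape
        k = self.kernel
        C = self._in_shape[2]
        flat_cols = self._cols.reshape(-1, k * C)
        flat_dy = dy.reshape(-1, F)
        self.grads[0][...] = flat_cols.T @ flat_dy
        self.grads[1][...] = flat_dy.sum(axis=0)
        dcols = (dy @ self.W.T).reshape(B, Lp, k, C)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for j in range(k):
            dx[:, j:j + Lp, :] += dcols[:, :, j, :]
        return dx


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(_Layer):
    """Per-filter normalisation over batch and length, Keras-style."""

    def __init__(self, channels: int, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(np.float32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_sd = 1.0 / np.sqrt(var + EPS)
        self._xhat = (x - mean) * self._inv_sd
        self._m = x.shape[0] * x.shape[1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        m = self._m
        self.grads[0][...] = np.sum(dy * self._xhat, axis=(0, 1))
        self.grads[1][...] = np.sum(dy, axis=(0, 1))
        dxhat = dy * self.gamma
        return (self._inv_sd / m) * (
            m * dxhat - dxhat.sum(axis=(0, 1))
            - self._xhat * np.sum(dxhat * self._xhat, axis=(0, 1)))


class MaxPool(_Layer):
    """Window 2, stride 1; ties route the gradient to the left element."""

    def out_length(self, length: int) -> int:
        return length - 1

    def forward(self, x, train):
        left, right = x[:, :-1, :], x[:, 1:, :]
        self._left_wins = left >= right
        return np.where(self._left_wins, left, right)

    def backward(self, dy):
        B, Lp, C = dy.shape
        dx = np.zeros((B, Lp + 1, C), dtype=np.float32)
        dl = dy * self._left_wins
        dr = dy * ~self._left_wins
        dx[:, :-1, :] += dl
        dx[:, 1:, :] += dr
        return dx


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu_gain: bool = True):
        scale = np.sqrt((2.0 if relu_gain else 1.0) / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


# ---------------------------------------------------------------------------
# network spec / builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnnSpec:
    """The fixed calibration architecture with per-attribute switches.

    conv stack: 32 -> (pool) -> 16,16,16,16 -> 32 -> 64 filters, kernel 3,
    stride 1, ReLU throughout; batchnorm after the first convolution; the
    max-pooling layer is omitted for ferulic acid; two hidden dense layers
    normally, three for ferulic acid and rosmarinic acid; one linear output.
    """

    use_batchnorm: bool = True
    use_maxpool: bool = True
    n_dense: int = 2
    dense_widths: tuple[int, ...] | None = None
    conv_filters: tuple[int, ...] = (32, 16, 16, 16, 16, 32, 64)
    kernel: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 50
    max_epochs: int = 200
    patience: int = 40

    def hidden_widths(self) -> tuple[int, ...]:
        if self.dense_widths is not None:
            return self.dense_widths
        if self.n_dense == 2:
            return (64, 16)
        if self.n_dense == 3:
            return (64, 32, 16)
        raise ParameterError(f"n_dense must be 2 or 3, got {self.n_dense}")

    @classmethod
    def for_attribute(cls, attribute: str, **overrides) -> "CnnSpec":
        """Per-attribute switches: no pooling for ferulic acid; a third
        dense layer for ferulic and rosmarinic acid."""
        kwargs = dict(
            use_maxpool=attribute != "ferulic_acid",
            n_dense=3 if attribute in ("ferulic_acid", "rosmarinic_acid") else 2,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


class Network:
    """An ordered layer stack with MSE loss and an Adam optimizer."""

    def __init__(self, layers: list[_Layer], seed: int):
        self.layers = layers
        self.seed = seed
        self._adam_m = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_v = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                m = self._adam_m[i]
                v = self._adam_v[i]
                m[...] = beta1 * m + (1 - beta1) * g
                v[...] = beta2 * v + (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)
                i += 1


def build_cnn(spec: CnnSpec, n_channels: int, seed: int = 0) -> Network:
    """Assemble the layer stack for ``n_channels`` input channels."""
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    length = n_channels
    in_ch = 1
    for j, filters in enumerate(spec.conv_filters):
        conv = Conv1D(in_ch, filters, spec.kernel, rng)
        layers.append(conv)
        length = conv.out_length(length)
        layers.append(ReLU())
        if j == 0:
            if spec.use_batchnorm:
                layers.append(BatchNorm(filters))
            if spec.use_maxpool:
                pool = MaxPool()
                layers.append(pool)
                length = pool.out_length(length)
        if length < 1:
            raise ArchitectureError(
                f"input of {n_channels} channels is shorter than the "
                f"receptive field of the convolution stack")
        in_ch = filters
    layers.append(Flatten())
    width = length * in_ch
    for w in spec.hidden_widths():
        layers.append(Dense(width, w, rng))
        layers.append(ReLU())
        width = w
    layers.append(Dense(width, 1, rng, relu_gain=False))
    return Network(layers, seed)


def receptive_field(spec: CnnSpec) -> int:
    """Minimum input length accepted by the stack."""
    shrink = len(spec.conv_filters) * (spec.kernel - 1)
    if spec.use_maxpool:
        shrink += 1
    return shrink + 1


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def train_network(net: Network, X: np.ndarray, y: np.ndarray, spec: CnnSpec,
                  seed: int = 0) -> TrainingHistory:
    """MSE minimisation with Adam; early stop when the epoch training loss
    has not improved for ``spec.patience`` epochs (final weights kept)."""
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32).ravel()
    if X.ndim == 2:
        X = X[:, :, np.newaxis]
    n = X.shape[0]
    rng = np.random.default_rng(seed + 1)
    history = TrainingHistory()
    best = np.inf
    since_best = 0
    for epoch in range(spec.max_epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = perm[start:start + spec.batch_size]
            xb, yb = X[idx], y[idx]
            pred = net.forward(xb, train=True).ravel()
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
            net.backward((2.0 / idx.size * resid)[:, np.newaxis]
                         .astype(np.float32))
            net.adam_step(spec.learning_rate)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.epoch_loss.append(epoch_loss)
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                history.stopped_epoch = epoch + 1
                break
    return history


def predict_network(net: Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, :, np.newaxis]
    outs = [net.forward(X[i:i + batch], train=False).ravel()
            for i in range(0, X.shape[0], batch)]
    return np.concatenate(outs).astype(float)
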