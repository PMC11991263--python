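"""Minimal NumPy neural-network layer kit with explicit forward/backward.

Every layer exposes

    forward(x, train) -> (y, cache)
    backward(cache, gy) -> gx          # accumulates into Param.grad

so a layer object may be applied several times per forward pass (weight
sharing across the two DMCNN input streams) — the caches live outside the
layer and parameter gradients simply accumulate across calls.

Feature maps are ``(N, C, L)`` float32 arrays (the usual deep-learning
precision; halves memory traffic on CPU); dense activations ``(N, F)``.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv1d", "BatchNorm1d", "ReLU", "Sigmoid", "MaxPool1d",
    "GlobalAvgPool1d", "Flatten", "Dropout", "Linear", "SEBlock", "Sequential",
    "SGD", "softmax", "cross_entropy_with_grad",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def shape(self):
        return self.value.shape


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """1-D cross-correlation with 'same' (stride-aware) padding.

    Padding replicates the boundary sample ("edge" mode) rather than
    zero-filling: a spectrum's continuum does not drop to zero at the ends
    of the wavelength grid, and a zero pad would manufacture a step edge
    that dominates early feature maps (and hence saliency maps) at the
    boundaries.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 pad_mode: str = "edge", bias: bool = True):
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.W = Param(_he_init(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.b = Param(np.zeros(out_channels)) if bias else None

    def params(self):
        return [self.W, self.b] if self.b is not None else [self.W]

    def _pad(self, L: int) -> tuple[int, int, int]:
        L_out = -(-L // self.stride)  # ceil
        total = max((L_out - 1) * self.stride + self.kernel_size - L, 0)
        return L_out, total // 2, total - total // 2

    def forward(self, x, train: bool = False):
        N, C, L = x.shape
        L_out, pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), mode=self.pad_mode)
        cols = sliding_window_view(xp, self.kernel_size, axis=2)[:, :, ::self.stride, :]
        # im2col + BLAS matmul: (N*L_out, C*k) @ (C*k, O)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)
                                     ).reshape(N * L_out, C * self.kernel_size)
        Wmat = self.W.value.reshape(self.out_channels, -1)
        y = (cols2 @ Wmat.T).reshape(N, L_out, self.out_channels).transpose(0, 2, 1)
        if self.b is not None:
            y = y + self.b.value[None, :, None]
        return np.ascontiguousarray(y), (cols2, x.shape, pl)

    def backward(self, cache, gy):
        cols2, xshape, pl = cache
        N, C, L = xshape
        L_out = gy.shape[2]
        gy2 = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(N * L_out, -1)
        self.W.grad += (gy2.T @ cols2).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += gy2.sum(axis=0)
        Wmat = self.W.value.reshape(self.out_channels, -1)
        gcols = (gy2 @ Wmat).reshape(N, L_out, C, self.kernel_size) \
                            .transpose(0, 2, 1, 3)
        _, _, pr = self._pad(L)
        gxp = np.zeros((N, C, L + pl + pr), dtype=gy.dtype)
        for i in range(self.kernel_size):
            gxp[:, :, i:i + L_out * self.stride:self.stride] += gcols[:, :, :, i]
        gx = gxp[:, :, pl:pl + L].copy()
        if self.pad_mode == "edge":
            # replicated samples are views of the boundary values, so their
            # gradients fold back onto the first/last grid point
            if pl:
                gx[:, :, 0] += gxp[:, :, :pl].sum(axis=2)
            if pr:
                gx[:, :, -1] += gxp[:, :, L + pl:].sum(axis=2)
        return gx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (N, L) axes of (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = False):
        axes = (0, 2) if x.ndim == 3 else (0,)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        y = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        return y, (xhat, invstd, train, x.ndim)

    def backward(self, cache, gy):
        xhat, invstd, train, ndim = cache
        axes = (0, 2) if ndim == 3 else (0,)
        shape = (1, -1, 1) if ndim == 3 else (1, -1)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value.reshape(shape)
        if not train:
            return g * invstd.reshape(shape)
        m = gy.size // gy.shape[1]
        gsum = g.sum(axis=axes).reshape(shape)
        gdot = (g * xhat).sum(axis=axes).reshape(shape)
        return (g - gsum / m - xhat * gdot / m) * invstd.reshape(shape)


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, gy):
        return gy * cache


class Sigmoid(Layer):
    def forward(self, x, train: bool = False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return y, y

    def backward(self, cache, gy):
        return gy * cache * (1.0 - cache)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, kernel_size: int):
        self.k = kernel_size

    def forward(self, x, train: bool = False):
        N, C, L = x.shape
        L_out = L // self.k
        xr = x[:, :, :L_out * self.k].reshape(N, C, L_out, self.k)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        return y, (idx, x.shape)

    def backward(self, cache, gy):
        idx, xshape = cache
        N, C, L = xshape
        L_out = L // self.k
        gxr = np.zeros((N, C, L_out, self.k), dtype=gy.dtype)
        np.put_along_axis(gxr, idx[..., None], gy[..., None], axis=3)
        gx = np.zeros(xshape, dtype=gy.dtype)
        gx[:, :, :L_out * self.k] = gxr.reshape(N, C, L_out * self.k)
        return gx


class GlobalAvgPool1d(Layer):
    def forward(self, x, train: bool = False):
        return x.mean(axis=2), x.shape

    def backward(self, cache, gy):
        N, C, L = cache
        return np.broadcast_to(gy[:, :, None] / L, (N, C, L)).copy()


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, cache, gy):
        return gy.reshape(cache)


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is true."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            return x, None
        keep = 1.0 - self.rate
        mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * mask, mask

    def backward(self, cache, gy):
        return gy if cache is None else gy * cache


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (in_features, out_features), in_features))
        self.b = Param(np.zeros(out_features))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = False):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, gy):
        self.W.grad += cache.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: per-channel global average over length. Excitation: two fully
    connected layers, z = sigmoid(W2 relu(W1 s)). Scale: each channel of the
    input map is multiplied by its weight z_c in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        rng = rng or np.random.default_rng(0)
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train: bool = False):
        N, C, L = x.shape
        s = x.mean(axis=2)                      # squeeze (N, C)
        h, c1 = self.fc1.forward(s, train)
        hr = np.maximum(h, 0.0)
        e, c2 = self.fc2.forward(hr, train)
        z = 1.0 / (1.0 + np.exp(-np.clip(e, -60, 60)))   # (N, C)
        y = x * z[:, :, None]
        return y, (x, s, c1, h, c2, z)

    def backward(self, cache, gy):
        x, s, c1, h, c2, z = cache
        N, C, L = x.shape
        gz = (gy * x).sum(axis=2)
        ge = gz * z * (1.0 - z)
        ghr = self.fc2.backward(c2, ge)
        gh = ghr * (h > 0)
        gs = self.fc1.backward(c1, gh)
        gx = gy * z[:, :, None] + gs[:, :, None] / L
        return gx


class Sequential(Layer):
    """A plain layer chain usable as a trainable model.

    Implements the model API expected by the training loop: ``forward``
    returns ``(logits, tape)`` and ``backward(tape, glogits)`` accumulates
    parameter gradients. ``feature_layers`` maps names to layer indices whose
    (convolutional) outputs can be targeted by Grad-CAM.
    """

    def __init__(self, layers: list[Layer], feature_layers: dict[str, int] | None = None):
        self.layers = layers
        self.feature_layers = feature_layers or {}
        self.default_target_layer = next(iter(self.feature_layers), None)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2 and isinstance(self.layers[0], Conv1d):
            x = x[:, None, :]          # (N, L) -> (N, 1, L)
        tape = []
        for layer in self.layers:
            x, cache = layer.forward(x, train)
            tape.append((cache, x))
        return x, tape

    def predict(self, x):
        logits, _ = self.forward(x, train=False)
        return logits.argmax(axis=1)

    def predict_proba(self, x):
        logits, _ = self.forward(x, train=False)
        return softmax(logits)

    def backward(self, tape, gy, stop_at: int | None = None):
        for i in range(len(self.layers) - 1, -1, -1):
            gy = self.layers[i].backward(tape[i][0], gy)
            if stop_at is not None and i == stop_at + 1:
                return gy
        return gy

    def gradcam_features(self, x, class_index: int, target_layer: str):
        """Return (logits, feature maps, gradients) at a named conv layer."""
        if target_layer not in self.feature_layers:
            raise ValueError(
                f"unknown target layer {target_layer!r}; "
                f"available: {sorted(self.feature_layers)}")
        li = self.feature_layers[target_layer]
        logits, tape = self.forward(x, train=False)
        # margin score: softmax logits are shift-invariant, so saliency
        # differentiates logit_k minus the mean of the other logits
        gy = np.full_like(logits, -1.0 / max(logits.shape[1] - 1, 1))
        gy[:, class_index] = 1.0
        grad = self.backward(tape, gy, stop_at=li)
        fmap = tape[li][1]
        if fmap.ndim != 3:
            raise ValueError(f"target layer {target_layer!r} is not a feature map")
        return logits, fmap, grad


class SGD:
    """Stochastic gradient descent with classical momentum and L2 decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-30, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n
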