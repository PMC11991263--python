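"""The double-stream multi-scale residual/channel-attention 1-D CNN.

The classifier ingests a single preprocessed spectrum of length
``input_length``.  A backward difference of the spectrum forms a second
input stream (rate of change of intensity with wavelength), giving two
streams x three convolution scales = six logical branches whose weights are
shared 2 x 3 across the streams:

    raw ──┐                        ┌─ conv k=1 ─┐
          ├─ per stream (shared): ─┼─ conv k=3 ─┼─ concat ─ maxpool ─ conv
    diff ─┘                        └─ conv k=5 ─┘
          → Res_Basic(+SE) → Res_Down(+SE, strided, 1x1 shortcut)
    streams fused by channel concatenation → flatten → MLP (hidden
    layers, 50% dropout) → class logits

Squeeze-and-excitation sits after the second normalisation and before the
final activation inside each residual block, per the reference design.
Training is plain mini-batch SGD on cross-entropy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (BatchNorm1d, Conv1d, Dropout, Flatten, Linear,
                  MaxPool1d, ReLU, SEBlock, SGD, cross_entropy_with_grad,
                  softmax)
from .spectra_io import SpectralDataset

__all__ = ["DMCNNConfig", "TrainConfig", "EvalResult", "DMCNN",
           "backward_difference", "build_model", "se_forward",
           "residual_forward", "split_dataset", "train", "evaluate",
           "ModelError", "TrainingDivergence"]


class ModelError(ValueError):
    """Raised for invalid model configuration or incompatible shapes."""


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; names the epoch."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DMCNNConfig:
    """Architecture hyperparameters.

    ``use_backward_difference`` and ``use_multiscale`` realise the ablation
    arms: both off = the residual/channel-attention base module.  Channel
    widths, SE reduction, pool size and MLP sizes are CPU-scale choices.
    """

    input_length: int = 2048
    kernel_sizes: tuple = (1, 3, 5)
    branch_channels: int = 16
    se_reduction: int = 4
    diff_step_h: int = 1
    dropout_rate: float = 0.5
    mlp_hidden: tuple = (256, 64)
    share_stream_weights: bool = True
    use_backward_difference: bool = True
    use_multiscale: bool = True
    n_classes: int = 2
    pool_size: int = 8
    down_channels: int = 64

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ModelError("dropout_rate must be in [0, 1)")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ModelError("kernel sizes must be odd")
        if self.diff_step_h < 1:
            raise ModelError("diff_step_h must be a positive integer")
        if self.se_reduction < 1:
            raise ModelError("se_reduction must be >= 1")
        if self.input_length < self.pool_size:
            raise ModelError("input_length shorter than pool_size")

    @property
    def merged_channels(self) -> int:
        return self.branch_channels * len(self.kernel_sizes)


@dataclass
class TrainConfig:
    """Optimisation settings.

    The reference protocol is SGD at learning rate 1e-5 for 300 epochs with
    a stratified 6:2:2 train/validation/test split; ``scaled_cpu`` gives a
    budget suitable for quick CPU runs on the synthetic task.
    """

    learning_rate: float = 1e-5
    epochs: int = 300
    batch_size: int = 32
    momentum: float = 0.9
    weight_decay: float = 0.0
    split_ratios: tuple = (0.6, 0.2, 0.2)
    seed: int = 0
    group_aware_split: bool = False

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ModelError("split_ratios must sum to 1")

    @classmethod
    def scaled_cpu(cls, seed: int = 0, epochs: int = 4,
                   learning_rate: float = 0.01,
                   weight_decay: float = 1e-3) -> "TrainConfig":
        return cls(learning_rate=learning_rate, epochs=epochs, seed=seed,
                   weight_decay=weight_decay)


@dataclass
class EvalResult:
    """Confusion counts (first class name = positive) and accuracy."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    train_accuracy_trace: list = field(default_factory=list)
    val_accuracy_trace: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def backward_difference(y: np.ndarray, h: int = 1) -> np.ndarray:
    """First-order backward difference, out[k] = (y[k] - y[k-h]) / h.

    Length-preserving: the first ``h`` entries, which have no left
    neighbour, are set to 0.  Works on a vector or on rows of a matrix.
    """
    y = np.asarray(y, dtype=float)
    L = y.shape[-1]
    if h <= 0 or h >= L:
        raise ModelError(f"difference step h={h} must satisfy 0 < h < {L}")
    out = np.zeros_like(y)
    out[..., h:] = (y[..., h:] - y[..., :-h]) / h
    return out


def _class_score_grad(logits: np.ndarray, class_index: int) -> np.ndarray:
    """Seed gradient for class-activation maps: the margin score.

    Softmax logits are only defined up to a shared offset, so the class
    score used for saliency is logit_k minus the mean of the other logits
    (for two classes, the logit margin).  Differentiating a raw logit
    instead would make the map depend on how the network happens to split
    evidence between the two redundant output units.
    """
    gy = np.full_like(logits, -1.0 / max(logits.shape[1] - 1, 1))
    gy[:, class_index] = 1.0
    return gy


def se_forward(features: np.ndarray, W1: np.ndarray, W2: np.ndarray,
               b1: "np.ndarray | float" = 0.0, b2: "np.ndarray | float" = 0.0
               ) -> np.ndarray:
    """Functional squeeze-excitation-scale on a (C, L) feature map.

    z = sigmoid(W2 @ relu(W1 @ mean_L(x) + b1) + b2); each channel is scaled
    by its weight z_c in (0, 1).
    """
    features = np.asarray(features, dtype=float)
    s = features.mean(axis=-1)                       # (C,)
    hidden = np.maximum(W1 @ s + b1, 0.0)
    z = 1.0 / (1.0 + np.exp(-(W2 @ hidden + b2)))
    return features * z[..., :, None]


def residual_forward(x: np.ndarray, block) -> np.ndarray:
    """Evaluate a residual block, y = F(x, {W_i}) + shortcut(x), in eval mode."""
    y, _ = block.forward(np.asarray(x, dtype=float)[None] if x.ndim == 2 else x,
                         train=False)
    return y[0] if x.ndim == 2 else y


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

class _ResBlock(_nn.Layer):
    """conv-BN-ReLU-conv-BN-SE (+ shortcut) -ReLU.

    ``Res_Basic``: identity shortcut, stride 1, equal channels.
    ``Res_Down``: strided first conv plus a 1x1-convolution shortcut so the
    skip path matches the main path's shape.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 se_reduction: int, rng: np.random.Generator,
                 use_se: bool = True):
        self.conv1 = Conv1d(in_channels, out_channels, 3, stride, rng,
                            bias=False)
        self.bn1 = BatchNorm1d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, 3, 1, rng, bias=False)
        self.bn2 = BatchNorm1d(out_channels)
        self.se = SEBlock(out_channels, se_reduction, rng) if use_se else None
        self.relu2 = ReLU()
        self.downsample = None
        if stride != 1 or in_channels != out_channels:
            self.downsample = Conv1d(in_channels, out_channels, 1, stride, rng)

    def params(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.se is not None:
            mods.append(self.se)
        if self.downsample is not None:
            mods.append(self.downsample)
        out = []
        for m in mods:
            out.extend(m.params())
        return out

    def forward(self, x, train: bool = False):
        h, c1 = self.conv1.forward(x, train)
        h, cb1 = self.bn1.forward(h, train)
        h, cr1 = self.relu1.forward(h, train)
        h, c2 = self.conv2.forward(h, train)
        h, cb2 = self.bn2.forward(h, train)
        cse = None
        if self.se is not None:
            h, cse = self.se.forward(h, train)
        if self.downsample is not None:
            sc, cd = self.downsample.forward(x, train)
        else:
            sc, cd = x, None
        y, cr2 = self.relu2.forward(h + sc, train)
        return y, (c1, cb1, cr1, c2, cb2, cse, cd, cr2)

    def backward(self, cache, gy):
        c1, cb1, cr1, c2, cb2, cse, cd, cr2 = cache
        g = self.relu2.backward(cr2, gy)
        gmain = self.se.backward(cse, g) if self.se is not None else g
        gmain = self.bn2.backward(cb2, gmain)
        gmain = self.conv2.backward(c2, gmain)
        gmain = self.relu1.backward(cr1, gmain)
        gmain = self.bn1.backward(cb1, gmain)
        gx = self.conv1.backward(c1, gmain)
        if self.downsample is not None:
            gx = gx + self.downsample.backward(cd, g)
        else:
            gx = gx + g
        return gx


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DMCNN:
    """Double-stream multi-scale residual/channel-attention classifier.

    Implements the model API used by :func:`train` (``forward`` ->
    ``(logits, tape)``, ``backward(tape, glogits)``) plus
    ``gradcam_features`` for saliency.  With ``share_stream_weights`` the
    raw and differenced streams run through the *same* layer objects, so
    the six branches carry 2 x 3 shared parameters.
    """

    FEATURE_LAYERS = ("scales", "msconv", "res_basic", "res_down")
    default_target_layer = "res_down"

    def __init__(self, cfg: DMCNNConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C = cfg.merged_channels
        pooled = cfg.input_length // cfg.pool_size
        self.down_length = -(-pooled // 2)       # after the strided Res_Down

        def make_stream():
            stream = {}
            if cfg.use_multiscale:
                stream["scale_convs"] = [Conv1d(1, cfg.branch_channels, k, 1,
                                                rng, bias=False)
                                         for k in cfg.kernel_sizes]
            else:
                stream["scale_convs"] = [Conv1d(1, C, 3, 1, rng, bias=False)]
            stream["scale_relu"] = ReLU()
            stream["pool"] = MaxPool1d(cfg.pool_size)
            stream["msconv"] = Conv1d(C, C, 3, 1, rng, bias=False)
            stream["msrelu"] = ReLU()
            stream["res_basic"] = _ResBlock(C, C, 1, cfg.se_reduction, rng)
            stream["res_down"] = _ResBlock(C, cfg.down_channels, 2,
                                           cfg.se_reduction, rng)
            return stream

        self.stream = make_stream()
        if cfg.use_backward_difference and not cfg.share_stream_weights:
            self.stream_diff = make_stream()
        else:
            self.stream_diff = self.stream      # shared storage

        self.flatten = Flatten()
        n_streams = 2 if cfg.use_backward_difference else 1
        feat = cfg.down_channels * self.down_length * n_streams
        self.mlp: list[_nn.Layer] = []
        for h in cfg.mlp_hidden:
            self.mlp.append(Linear(feat, h, rng))
            self.mlp.append(ReLU())
            feat = h
        self.dropout = Dropout(cfg.dropout_rate, np.random.default_rng(seed + 1))
        self.head = Linear(feat, cfg.n_classes, rng)

    # -- parameters --------------------------------------------------------
    def params(self):
        seen: set[int] = set()
        out = []
        streams = [self.stream]
        if self.stream_diff is not self.stream:
            streams.append(self.stream_diff)
        for st in streams:
            mods = st["scale_convs"] + [st["msconv"], st["res_basic"], st["res_down"]]
            for m in mods:
                for p in m.params():
                    if id(p) not in seen:
                        seen.add(id(p))
                        out.append(p)
        for m in self.mlp + [self.head]:
            out.extend(m.params())
        return out

    # -- forward / backward ------------------------------------------------
    def _stream_forward(self, st, x, train):
        caches = {}
        outs, ccaches = [], []
        for conv in st["scale_convs"]:
            o, c = conv.forward(x, train)
            outs.append(o)
            ccaches.append(c)
        merged = np.concatenate(outs, axis=1)
        caches["scale_convs"] = (ccaches, [o.shape[1] for o in outs])
        act, caches["scale_relu"] = st["scale_relu"].forward(merged, train)
        caches["scales_map"] = act
        pooled, caches["pool"] = st["pool"].forward(act, train)
        h, caches["msconv"] = st["msconv"].forward(pooled, train)
        caches["msconv_map"] = h
        h, caches["msrelu"] = st["msrelu"].forward(h, train)
        h, caches["res_basic"] = st["res_basic"].forward(h, train)
        caches["res_basic_map"] = h
        h, caches["res_down"] = st["res_down"].forward(h, train)
        caches["res_down_map"] = h
        return h, caches

    def _stream_backward(self, st, caches, gy, stop_at: "str | None" = None):
        g = st["res_down"].backward(caches["res_down"], gy)
        if stop_at == "res_basic":
            return g
        g = st["res_basic"].backward(caches["res_basic"], g)
        g = st["msrelu"].backward(caches["msrelu"], g)
        if stop_at == "msconv":
            return g
        g = st["msconv"].backward(caches["msconv"], g)
        g = st["pool"].backward(caches["pool"], g)
        g = st["scale_relu"].backward(caches["scale_relu"], g)
        if stop_at == "scales":
            return g
        ccaches, widths = caches["scale_convs"]
        gx = None
        start = 0
        for conv, c, w in zip(st["scale_convs"], ccaches, widths):
            gpart = conv.backward(c, g[:, start:start + w])
            gx = gpart if gx is None else gx + gpart
            start += w
        return gx

    def forward(self, x: np.ndarray, train: bool = False):
        """``x``: (N, L) spectra. Returns (logits, tape)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.cfg.input_length:
            raise ModelError(
                f"expected spectra of length {self.cfg.input_length}, got {x.shape[1]}")
        tape: dict = {}
        x3 = x[:, None, :]
        out_raw, tape["raw"] = self._stream_forward(self.stream, x3, train)
        feats = [out_raw]
        if self.cfg.use_backward_difference:
            xd = backward_difference(x, self.cfg.diff_step_h).astype(np.float32)[:, None, :]
            out_diff, tape["diff"] = self._stream_forward(self.stream_diff, xd, train)
            feats.append(out_diff)
        fused = np.concatenate(feats, axis=1)
        tape["fuse_widths"] = [f.shape[1] for f in feats]
        h, tape["flatten"] = self.flatten.forward(fused, train)
        tape["mlp"] = []
        for layer in self.mlp:
            h, c = layer.forward(h, train)
            tape["mlp"].append(c)
        h, tape["dropout"] = self.dropout.forward(h, train)
        logits, tape["head"] = self.head.forward(h, train)
        return logits, tape

    def backward(self, tape, glogits, stop_at: "str | None" = None,
                 stop_stream: str = "raw"):
        g = self.head.backward(tape["head"], glogits)
        g = self.dropout.backward(tape["dropout"], g)
        for layer, c in zip(reversed(self.mlp), reversed(tape["mlp"])):
            g = layer.backward(c, g)
        g = self.flatten.backward(tape["flatten"], g)
        widths = tape["fuse_widths"]
        g_raw = g[:, :widths[0]]
        if stop_at == "res_down" and stop_stream == "raw":
            return g_raw
        if stop_at is not None and stop_stream == "raw":
            return self._stream_backward(self.stream, tape["raw"], g_raw, stop_at)
        gx = self._stream_backward(self.stream, tape["raw"], g_raw)
        if self.cfg.use_backward_difference:
            g_diff = g[:, widths[0]:]
            if stop_at is not None:
                return self._stream_backward(self.stream_diff, tape["diff"],
                                             g_diff, stop_at)
            gd = self._stream_backward(self.stream_diff, tape["diff"], g_diff)
            # chain through the backward difference of the input
            h = self.cfg.diff_step_h
            gd = gd[:, 0, :]
            gxd = np.zeros_like(gd)
            gxd[:, h:] += gd[:, h:] / h
            gxd[:, :-h] -= gd[:, h:] / h
            gx = gx + gxd[:, None, :]
        return gx

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return softmax(logits)

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return logits.argmax(axis=1)

    def gradcam_features(self, x: np.ndarray, class_index: int,
                         target_layer: str = "res_down"):
        """Logits plus feature map and class-score gradient at a named layer.

        The map is taken from the raw-spectrum stream (wavelength aligned).
        """
        if target_layer not in self.FEATURE_LAYERS:
            raise ModelError(f"unknown target layer {target_layer!r}; "
                             f"choose from {self.FEATURE_LAYERS}")
        logits, tape = self.forward(x, train=False)
        gy = _class_score_grad(logits, class_index)
        fmap = tape["raw"][target_layer + "_map"]
        grad = self.backward_nogradacc(tape, gy, stop_at=target_layer)
        return logits, fmap, grad

    def backward_nogradacc(self, tape, gy, stop_at: str):
        """Input-direction backward pass that leaves parameter grads untouched."""
        params = self.params()
        saved = [p.grad.copy() for p in params]
        grad = self.backward(tape, gy, stop_at=stop_at, stop_stream="raw")
        for p, s in zip(params, saved):
            p.grad[...] = s
        return grad

    def feature_map_stride(self, target_layer: str) -> int:
        """Input-grid points per feature-map sample at a target layer."""
        if target_layer == "scales":
            return 1
        if target_layer in ("msconv", "res_basic"):
            return self.cfg.pool_size
        if target_layer == "res_down":
            return self.cfg.pool_size * 2
        raise ModelError(f"unknown target layer {target_layer!r}")


def build_model(cfg: "DMCNNConfig | None" = None, seed: int = 0) -> DMCNN:
    """Construct a DMCNN; raises :class:`ModelError` on invalid configs."""
    return DMCNN(cfg or DMCNNConfig(), seed=seed)


# ---------------------------------------------------------------------------
# splitting, training, evaluation
# ---------------------------------------------------------------------------

def _partition_counts(n: int, ratios) -> list[int]:
    sizes = [int(np.floor(r * n)) for r in ratios[1:]]
    return [n - sum(sizes)] + sizes    # remainder goes to the first (train)


def split_dataset(ds: SpectralDataset, ratios=(0.6, 0.2, 0.2), seed: int = 0,
                  group_aware: bool = False):
    """Stratified partition into len(ratios) subsets (train first).

    Per class, each non-train partition receives floor(ratio * n_class)
    spectra and the remainder goes to train, so 2000 spectra at 6:2:2 give
    1200/400/400 and at 7:3 give 1400/600.  With ``group_aware`` whole
    tablets are assigned to one partition (no tablet spans two subsets).
    """
    ratios = tuple(ratios)
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ModelError("ratios must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in ratios]
    for c in range(len(ds.class_names)):
        idx = np.flatnonzero(ds.labels == c)
        if len(idx) == 0:
            continue
        if len(idx) < len(ratios):
            raise ModelError(
                f"class {ds.class_names[c]!r} has fewer spectra ({len(idx)}) "
                f"than partitions ({len(ratios)})")
        if group_aware:
            tablets = list(dict.fromkeys(ds.groups[idx]))
            order = rng.permutation(len(tablets))
            counts = _partition_counts(len(tablets), ratios)
            pos = 0
            for p, cnt in enumerate(counts):
                chosen = {tablets[order[j]] for j in range(pos, pos + cnt)}
                parts[p].extend(i for i in idx if ds.groups[i] in chosen)
                pos += cnt
        else:
            order = rng.permutation(len(idx))
            counts = _partition_counts(len(idx), ratios)
            pos = 0
            for p, cnt in enumerate(counts):
                parts[p].extend(idx[order[pos:pos + cnt]])
                pos += cnt
    return tuple(ds.subset(sorted(p)) for p in parts)


def _accuracy(model, X, y, batch: int = 256) -> float:
    correct = 0
    for i in range(0, len(X), batch):
        correct += int((model.predict(X[i:i + batch]) == y[i:i + batch]).sum())
    return correct / len(X)


def train(model, train_set: SpectralDataset, val_set: "SpectralDataset | None",
          tcfg: "TrainConfig | None" = None, verbose: bool = False):
    """Mini-batch SGD on cross-entropy; returns (model, EvalResult traces).

    Per-epoch train/validation accuracies are recorded; a non-finite loss
    aborts with :class:`TrainingDivergence` naming the epoch.
    """
    tcfg = tcfg or TrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    X = np.asarray(train_set.intensities, dtype=float)
    y = train_set.labels
    Xv = np.asarray(val_set.intensities, dtype=float) if val_set is not None else None
    yv = val_set.labels if val_set is not None else None

    opt = SGD(model.params(), lr=tcfg.learning_rate, momentum=tcfg.momentum,
              weight_decay=tcfg.weight_decay)
    train_trace, val_trace = [], []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(X))
        for i in range(0, len(X), tcfg.batch_size):
            bidx = order[i:i + tcfg.batch_size]
            opt.zero_grad()
            logits, tape = model.forward(X[bidx], train=True)
            loss, glogits = cross_entropy_with_grad(logits, y[bidx])
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch + 1}")
            model.backward(tape, glogits)
            opt.step()
        train_trace.append(_accuracy(model, X, y))
        if Xv is not None and len(Xv):
            val_trace.append(_accuracy(model, Xv, yv))
        if verbose:
            va = f" val={val_trace[-1]:.3f}" if val_trace else ""
            print(f"epoch {epoch + 1:3d}: train={train_trace[-1]:.3f}{va}")

    history = EvalResult(0, 0, 0, 0,
                         accuracy=train_trace[-1] if train_trace else 0.0,
                         train_accuracy_trace=train_trace,
                         val_accuracy_trace=val_trace)
    return model, history


def evaluate(model, test_set: SpectralDataset,
              history: "EvalResult | None" = None) -> EvalResult:
    """Confusion counts and accuracy = (TP+TN)/(TP+TN+FP+FN) on a test set.

    The first class name is the positive class; with more than two classes
    the negative cell aggregates all other correct predictions.
    """
    if len(test_set) == 0:
        raise ModelError("empty test set")
    X = np.asarray(test_set.intensities, dtype=float)
    y = test_set.labels
    pred = np.concatenate([model.predict(X[i:i + 256])
                           for i in range(0, len(X), 256)])
    tp = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred != 0) & (y == 0)))
    fp = int(np.sum((pred == 0) & (y != 0)))
    tn = int(np.sum((pred != 0) & (y != 0)))
    acc = float(np.mean(pred == y))
    return EvalResult(tp=tp, tn=tn, fp=fp,
                      fn=fn, accuracy=acc,
                      train_accuracy_trace=history.train_accuracy_trace if history else [],
                      val_accuracy_trace=history.val_accuracy_trace if history else [])
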