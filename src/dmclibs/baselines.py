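"""Comparison suite: classical ML classifiers and 1-D CNN references.

KNN / random forest / decision tree run through scikit-learn with the
reference parameter set (n_neighbors=5; n_estimators=100, random_state=42;
random_state=42) on a stratified 7:3 split, scored by held-out confusion
counts and mean five-fold cross-validation accuracy on the training
portion.

LeNet, a modified AlexNet (the max-pools of the first two stages replaced
by batch normalisation, everything else unchanged) and ResNet18 are 1-D
adaptations built on the same layer kit as the main classifier; canonical
layer counts are kept while channel widths are reduced to CPU scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from ._nn import (BatchNorm1d, Conv1d, Dropout, Flatten, GlobalAvgPool1d,
                  Linear, MaxPool1d, ReLU, Sequential)
from .dmcnn import EvalResult, ModelError, _ResBlock, split_dataset
from .spectra_io import SpectralDataset

__all__ = ["MLSpec", "run_ml", "build_classic_cnn", "accuracy_from_counts",
           "CLASSIC_CNNS", "ML_METHODS"]

ML_METHODS = ("knn", "rf", "dt")
CLASSIC_CNNS = ("lenet", "alexnet_mod", "resnet18")


@dataclass
class MLSpec:
    """Classical-ML settings mirroring the reference parameter table."""

    method: str = "rf"
    n_neighbors: int = 5
    n_estimators: int = 100
    random_state: int = 42
    cv_folds: int = 5

    def __post_init__(self):
        if self.method not in ML_METHODS:
            raise ModelError(f"unknown ML method {self.method!r}; "
                             f"choose from {ML_METHODS}")

    def make(self):
        if self.method == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors)
        if self.method == "rf":
            return RandomForestClassifier(n_estimators=self.n_estimators,
                                          random_state=self.random_state)
        return DecisionTreeClassifier(random_state=self.random_state)


def run_ml(ds: SpectralDataset, spec: MLSpec, ratios=(0.7, 0.3), seed: int = 0):
    """Fit a classical classifier on a stratified split.

    Returns ``(EvalResult, cv_accuracy)``: held-out confusion counts plus
    the mean ``cv_folds``-fold cross-validation accuracy computed on the
    training portion (folds shuffled under ``seed``).
    """
    train_set, test_set = split_dataset(ds, ratios, seed=seed)
    clf = spec.make()
    Xtr, ytr = train_set.intensities, train_set.labels
    Xte, yte = test_set.intensities, test_set.labels
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    tp = int(np.sum((pred == 0) & (yte == 0)))
    fn = int(np.sum((pred != 0) & (yte == 0)))
    fp = int(np.sum((pred == 0) & (yte != 0)))
    tn = int(np.sum((pred != 0) & (yte != 0)))
    result = EvalResult(tp=tp, tn=tn, fp=fp, fn=fn,
                        accuracy=float(np.mean(pred == yte)))
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    cv_acc = float(cross_val_score(spec.make(), Xtr, ytr, cv=cv,
                                   scoring="accuracy").mean())
    return result, cv_acc


def accuracy_from_counts(correct_per_class, total: int) -> float:
    """Accuracy percentage, 100 * (TP + TN) / n, to one decimal place."""
    if total <= 0:
        raise ModelError("total must be positive")
    correct = int(np.sum(correct_per_class))
    if correct > total:
        raise ModelError("correct counts exceed the total")
    return round(100.0 * correct / total, 1)


# ---------------------------------------------------------------------------
# classic 1-D CNNs
# ---------------------------------------------------------------------------

def _lenet(input_length: int, n_classes: int, rng) -> Sequential:
    # conv5-pool2-conv5-pool2-FC120-FC84-FC(n), widths as in the original
    layers = [
        Conv1d(1, 6, 5, 1, rng), ReLU(), MaxPool1d(2),
        Conv1d(6, 16, 5, 1, rng), ReLU(), MaxPool1d(2),
        Flatten(),
        Linear(16 * (input_length // 4), 120, rng), ReLU(),
        Linear(120, 84, rng), ReLU(),
        Linear(84, n_classes, rng),
    ]
    return Sequential(layers, feature_layers={"conv1": 0, "conv2": 3})


def _alexnet_mod(input_length: int, n_classes: int, rng) -> Sequential:
    # five conv stages at reduced widths; the first two stages carry
    # BatchNorm1d where AlexNet's MaxPool1d layers would sit
    L = -(-input_length // 4)          # stride-4 stem
    L3 = L // 2                        # single remaining pool
    layers = [
        Conv1d(1, 16, 11, 4, rng), ReLU(), BatchNorm1d(16),   # pool -> BN
        Conv1d(16, 32, 5, 1, rng), ReLU(), BatchNorm1d(32),   # pool -> BN
        Conv1d(32, 48, 3, 1, rng), ReLU(),
        Conv1d(48, 48, 3, 1, rng), ReLU(),
        Conv1d(48, 32, 3, 1, rng), ReLU(), MaxPool1d(2),
        Flatten(),
        Linear(32 * L3, 256, rng), ReLU(), Dropout(0.5, rng),
        Linear(256, 128, rng), ReLU(), Dropout(0.5, rng),
        Linear(128, n_classes, rng),
    ]
    return Sequential(layers, feature_layers={"conv1": 0, "conv5": 12})


def _resnet18(input_length: int, n_classes: int, rng) -> Sequential:
    # stem + 4 stages x 2 basic residual blocks, widths reduced for 1-D CPU use
    widths = (16, 32, 64, 128)
    layers: list = [Conv1d(1, widths[0], 7, 2, rng), BatchNorm1d(widths[0]),
                    ReLU(), MaxPool1d(2)]
    in_ch = widths[0]
    for si, w in enumerate(widths):
        stride = 1 if si == 0 else 2
        layers.append(_ResBlock(in_ch, w, stride, se_reduction=1, rng=rng, use_se=False))
        layers.append(_ResBlock(w, w, 1, se_reduction=1, rng=rng, use_se=False))
        in_ch = w
    layers += [GlobalAvgPool1d(), Linear(widths[-1], n_classes, rng)]
    return Sequential(layers, feature_layers={"stem": 0, "stage4": len(layers) - 3})


def build_classic_cnn(name: str, input_length: int = 2048, n_classes: int = 2,
                      seed: int = 0) -> Sequential:
    """Build a 1-D LeNet, modified AlexNet or ResNet18."""
    rng = np.random.default_rng(seed)
    if name == "lenet":
        return _lenet(input_length, n_classes, rng)
    if name == "alexnet_mod":
        return _alexnet_mod(input_length, n_classes, rng)
    if name == "resnet18":
        return _resnet18(input_length, n_classes, rng)
    raise ModelError(f"unknown classic CNN {name!r}; choose from {CLASSIC_CNNS}")
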