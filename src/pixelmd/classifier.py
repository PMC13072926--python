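"""CNN state classifier with chronology-aware grouped five-fold CV.

The architecture is fixed by configuration: four 3x3 convolution layers
(32, 32, 64, 64 kernels, ReLU), a 2x2 max-pool + dropout 0.25 after every
two convolutions, one 512-unit ReLU dense layer with dropout 0.5, and a
2-way softmax output trained with categorical cross-entropy.

Because consecutive MD frames are strongly autocorrelated, a plain random
split would leak near-duplicate frames between train and validation.  The
fold assignment therefore cuts each trajectory into 10 contiguous
chronological groups, splits each group into 5 contiguous sub-blocks, and
lets fold f validate on the f-th sub-block of every group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import Conv2D, ConvNet, Dense, Dropout, Flatten, MaxPool2, ReLU
from .encoding import PixelMapDataset

__all__ = [
    "ClassifierConfig",
    "FoldAssignment",
    "ConfusionCounts",
    "TrainedClassifier",
    "CVResult",
    "make_fold_assignment",
    "build_network",
    "train_classifier",
    "accuracy",
    "cross_validate",
]

N_GROUPS = 10
N_FOLDS = 5


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture + optimization settings for the state classifier."""

    conv_kernels: tuple[int, ...] = (32, 32, 64, 64)
    conv_dropout: float = 0.25
    dense_units: int = 512
    dense_dropout: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    patience: int = 2
    validation_fraction: float = 0.1
    convergence_loss: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.conv_dropout < 1.0 or not 0.0 <= self.dense_dropout < 1.0:
            raise ValueError("dropout rates must be in [0, 1)")
        if len(self.conv_kernels) % 2 != 0:
            raise ValueError("conv kernels must come in pairs (pool after every two)")


def build_network(config: ClassifierConfig, input_shape: tuple[int, int, int],
                  n_classes: int = 2, seed: int | None = None) -> ConvNet:
    """Assemble the CNN for a given image shape.

    Two 2x2 pools require the image to be at least 4x4.
    """
    h, w, c = input_shape
    n_pools = len(config.conv_kernels) // 2
    if h < 2 ** n_pools or w < 2 ** n_pools:
        raise ValueError(f"image {h}x{w} too small for {n_pools} 2x2 poolings")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layers = []
    c_in = c
    hh, ww = h, w
    for i, k in enumerate(config.conv_kernels):
        layers += [Conv2D(c_in, k, rng), ReLU()]
        c_in = k
        if i % 2 == 1:
            layers += [MaxPool2(), Dropout(config.conv_dropout)]
            hh, ww = hh // 2, ww // 2
    layers += [
        Flatten(),
        Dense(hh * ww * c_in, config.dense_units, rng),
        ReLU(),
        Dropout(config.dense_dropout),
        Dense(config.dense_units, n_classes, rng),
    ]
    net = ConvNet(layers, n_classes=n_classes,
                  seed=(config.seed if seed is None else seed))
    return net


# ---------------------------------------------------------------------------
# fold assignment


@dataclass
class FoldAssignment:
    """Per-frame (trajectory, chronological group, fold) labels."""

    trajectory: np.ndarray  # per frame
    group: np.ndarray       # 1..10, per frame
    fold: np.ndarray        # 1..5, per frame

    @property
    def n_frames(self) -> int:
        return len(self.fold)

    def val_indices(self, f: int) -> np.ndarray:
        if not 1 <= f <= N_FOLDS:
            raise ValueError(f"fold must be 1..{N_FOLDS}")
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        if not 1 <= f <= N_FOLDS:
            raise ValueError(f"fold must be 1..{N_FOLDS}")
        return np.flatnonzero(self.fold != f)


def make_fold_assignment(frame_counts: list[int]) -> FoldAssignment:
    """Chronological grouped CV labels for concatenated trajectories.

    Each trajectory is cut into 10 contiguous equal-size groups; each group
    into 5 contiguous sub-blocks.  Remainder frames are appended to the
    last group / last sub-block.  Fold f's validation set is the union of
    every group's f-th sub-block.
    """
    traj, group, fold = [], [], []
    for tid, n in enumerate(frame_counts):
        if n < N_GROUPS * N_FOLDS:
            raise ValueError(
                f"trajectory {tid} has {n} frames; need >= {N_GROUPS * N_FOLDS}"
            )
        g_size = n // N_GROUPS
        g_bounds = [0] + [g_size * i for i in range(1, N_GROUPS)] + [n]
        for g in range(N_GROUPS):
            lo, hi = g_bounds[g], g_bounds[g + 1]
            m = hi - lo
            s_size = m // N_FOLDS
            s_bounds = [0] + [s_size * i for i in range(1, N_FOLDS)] + [m]
            for f in range(N_FOLDS):
                cnt = s_bounds[f + 1] - s_bounds[f]
                traj += [tid] * cnt
                group += [g + 1] * cnt
                fold += [f + 1] * cnt
    return FoldAssignment(
        trajectory=np.array(traj), group=np.array(group), fold=np.array(fold)
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FN + FP + TN)."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    return (counts.tp + counts.tn) / counts.total


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1) -> ConfusionCounts:
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedClassifier:
    """A fitted network plus the label <-> index mapping."""

    network: ConvNet
    classes: np.ndarray  # class labels, index = network output unit
    history: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(images)

    def predict_labels(self, images: np.ndarray) -> np.ndarray:
        return self.classes[self.network.predict(images)]

    def encode_labels(self, labels: np.ndarray) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.array([idx[l] for l in labels])


def train_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
    seed: int | None = None,
    log=None,
) -> TrainedClassifier:
    """Train the CNN on uint8 pixel maps with string state labels."""
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[l] for l in labels])
    net = build_network(config, images.shape[1:], n_classes=len(classes), seed=seed)
    history = net.fit(
        images, y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        validation_fraction=config.validation_fraction,
        patience=config.patience,
        convergence_loss=config.convergence_loss,
        log=log,
    )
    return TrainedClassifier(network=net, classes=classes, history=history)


@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    fold_accuracies: list[float]
    mean_accuracy: float
    models: list[TrainedClassifier]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": f + 1, "TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn,
             "accuracy": a}
            for f, (c, a) in enumerate(zip(self.fold_counts, self.fold_accuracies))
        ]
        return pd.DataFrame(rows)


def cross_validate(
    dataset: PixelMapDataset,
    folds: FoldAssignment,
    config: ClassifierConfig,
    keep_models: bool = True,
    log=None,
) -> CVResult:
    """Grouped five-fold cross-validation; one model per fold.

    Per-fold seeds are derived deterministically from the config seed; the
    positive class for the confusion counts is the lexicographically second
    state label.
    """
    if folds.n_frames != dataset.n_samples:
        raise ValueError("fold assignment does not match dataset size")
    classes = dataset.classes
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[l] for l in dataset.labels])
    counts, accs, models = [], [], []
    for f in range(1, N_FOLDS + 1):
        seed_f = (config.seed * 1_000_003 + f) % (2 ** 31)
        tr = folds.train_indices(f)
        va = folds.val_indices(f)
        clf = train_classifier(
            dataset.images[tr], dataset.labels[tr], config, seed=seed_f, log=log
        )
        pred = clf.network.predict(dataset.images[va])
        c = _confusion(y[va], pred, positive=1)
        counts.append(c)
        accs.append(accuracy(c))
        if log:
            log(f"fold {f}: accuracy={accs[-1]:.4f} ({c})")
        models.append(clf if keep_models else None)
    return CVResult(
        fold_counts=counts,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        models=[m for m in models if m is not None],
    )
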