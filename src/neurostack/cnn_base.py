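"""Encoder-specific CNN base classifiers with grid-search tuning.

One convolutional network per encoder, convolving along sequence positions
(or dipeptide bins for the g-gap encoding) with the encoder's feature
columns as channels. Hyperparameters are tuned by grid search with mean
AUC over stratified k-fold cross-validation as the selection criterion.

Input channels are standardized (per-channel mean/std fit on the training
set and stored with the model) so that raw-unit encodings such as AAIndex,
whose columns span several orders of magnitude, train on comparable scales.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .encoders import ENCODER_IDS, EncodedMatrix
from .nn import SequenceConvNet


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters for one base classifier."""

    encoder_id: str
    conv_channels: tuple[int, ...] = (32,)
    kernel_sizes: tuple[int, ...] = (5,)
    pool: str = "max"
    dropout: float = 0.5
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_id not in ENCODER_IDS:
            raise ValueError(f"unknown encoder id {self.encoder_id!r}")
        if len(self.conv_channels) != len(self.kernel_sizes) or not self.conv_channels:
            raise ValueError("conv_channels and kernel_sizes must be equal-length, non-empty")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if self.pool not in ("max", "mean", "flatten"):
            raise ValueError(f"pool must be 'max', 'mean' or 'flatten', got {self.pool!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedBaseModel:
    """A fitted CNN bound to its encoder, with its input standardizer."""

    config: CNNConfig
    net: SequenceConvNet
    channel_mean: np.ndarray
    channel_std: np.ndarray

    @property
    def encoder_id(self) -> str:
        return self.config.encoder_id

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.channel_mean) / self.channel_std


def _stack(X: Sequence[EncodedMatrix] | np.ndarray, encoder_id: str) -> np.ndarray:
    """Coerce a list of EncodedMatrix (or a pre-stacked array) to (n, L, C)."""
    if isinstance(X, np.ndarray):
        if X.ndim != 3:
            raise ValueError("pre-stacked input must be 3-D (n, rows, cols)")
        return X
    mats = []
    for m in X:
        if m.encoder_id != encoder_id:
            raise ValueError(
                f"encoder mismatch: model is bound to {encoder_id!r}, got {m.encoder_id!r}"
            )
        mats.append(m.values)
    return np.stack(mats)


def build_cnn(config: CNNConfig, input_shape: tuple[int, int]) -> SequenceConvNet:
    """Instantiate the untrained network for a given encoder output shape."""
    return SequenceConvNet(
        in_len=input_shape[0],
        in_ch=input_shape[1],
        conv_channels=config.conv_channels,
        kernel_sizes=config.kernel_sizes,
        pool=config.pool,
        dropout=config.dropout,
        dense_units=config.dense_units,
        seed=config.seed,
    )


def train_cnn(
    X: Sequence[EncodedMatrix] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    config: CNNConfig,
) -> TrainedBaseModel:
    """Fit one base classifier; deterministic for a fixed ``config.seed``."""
    Xs = _stack(X, config.encoder_id)
    y = np.asarray(y, dtype=float)
    if len(Xs) != len(y) or len(y) < 2:
        raise ValueError("need at least 2 samples with matching labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    mean = Xs.mean(axis=(0, 1), keepdims=False)
    std = Xs.std(axis=(0, 1))
    std = np.where(std < 1e-8, 1.0, std)
    net = build_cnn(config, input_shape=Xs.shape[1:])
    net.fit(
        (Xs - mean) / std,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    return TrainedBaseModel(config=config, net=net, channel_mean=mean, channel_std=std)


def predict_proba(
    model: TrainedBaseModel, X: Sequence[EncodedMatrix] | np.ndarray
) -> np.ndarray:
    """Positive-class probability per input, order-preserving."""
    Xs = _stack(X, model.encoder_id)
    return model.net.predict_proba(model.standardize(Xs))


@dataclass(frozen=True)
class GridSearchSpace:
    """Candidate lists per hyperparameter; mean k-fold AUC is the criterion."""

    encoder_id: str
    grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {
            "conv_channels": [(16,), (32,), (64,)],
            "kernel_sizes": [(3,), (5,), (7,)],
            "learning_rate": [1e-3, 1e-4],
            "dropout": [0.3, 0.5],
        }
    )
    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must have non-empty candidate lists")

    def combinations(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*self.grid.values())]


def cross_val_auc(
    X: np.ndarray, y: np.ndarray, config: CNNConfig, k: int, seed: int
) -> list[float]:
    """Per-fold held-out AUC of a config under stratified k-fold CV."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("a CV fold contains a single class; reduce k or rebalance")
        model = train_cnn(X[train_idx], y[train_idx], config)
        scores = predict_proba(model, X[test_idx])
        aucs.append(float(roc_auc_score(y[test_idx], scores)))
    return aucs


def grid_search(
    space: GridSearchSpace,
    X: Sequence[EncodedMatrix] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    seed: int = 0,
    base_config: CNNConfig | None = None,
) -> tuple[CNNConfig, pd.DataFrame]:
    """Score every hyperparameter combination by mean CV AUC; return the best.

    Ties break toward the earliest-enumerated combination. The report table
    has one row per combination with its per-fold and mean AUC.
    """
    base = base_config or CNNConfig(encoder_id=space.encoder_id, seed=seed)
    Xs = _stack(X, space.encoder_id)
    y = np.asarray(y)
    rows = []
    best_idx, best_auc = 0, -np.inf
    for i, combo in enumerate(space.combinations()):
        config = replace(base, **combo)
        fold_aucs = cross_val_auc(Xs, y, config, k=space.k, seed=seed)
        mean_auc = float(np.mean(fold_aucs))
        rows.append({**{k: str(v) for k, v in combo.items()},
                     "mean_auc": mean_auc,
                     **{f"fold{j}_auc": a for j, a in enumerate(fold_aucs)}})
        if mean_auc > best_auc:
            best_idx, best_auc = i, mean_auc
    table = pd.DataFrame(rows)
    best = replace(base, **space.combinations()[best_idx])
    return best, table


def default_base_configs(seed: int = 0, epochs: int = 50) -> dict[str, CNNConfig]:
    """One default config per encoder, sharing a seed.

    The sequence-axis encoders (onehot, aaindex, word2vec) use global max
    pooling with a 64-filter bank and dropout 0.3: a motif is a
    translation-invariant local pattern, and the wider bank keeps held-out
    AUC stable across initialization seeds. The g-gap encoder keeps the
    position axis (``pool="flatten"``): its first axis indexes dipeptide
    bins, where position is identity, not context, and pooling it away
    would erase which pair occurred.
    """
    configs = {}
    for eid in ENCODER_IDS:
        if eid == "ggap":
            configs[eid] = CNNConfig(
                encoder_id=eid, seed=seed, epochs=epochs,
                pool="flatten", conv_channels=(32,), kernel_sizes=(3,),
            )
        else:
            configs[eid] = CNNConfig(
                encoder_id=eid, seed=seed, epochs=epochs,
                conv_channels=(64,), dropout=0.3,
            )
    return configs
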