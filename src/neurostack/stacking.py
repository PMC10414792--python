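"""Stacked ensemble: out-of-fold meta-features + Gaussian naive Bayes.

The four encoder-specific CNNs are combined by stacking: each training
sample's meta-feature vector holds the four base-classifier probabilities
(fixed column order onehot, aaindex, ggap, word2vec) produced
out-of-fold — every sample is scored by the base model whose training folds
excluded it, so the meta-learner never sees leaked predictions. For new
samples the base models are refit on the full training set.

The meta-learner is a Gaussian naive Bayes classifier implemented from
first principles: per class c and feature j the likelihood is
Normal(x_j; mu_cj, var_cj) with class-conditionally independent features,
priors are class frequencies, variances use the population divisor plus a
smoothing floor, and the posterior is computed in log space. Four
alternative meta-algorithms (logistic regression, AdaBoost, GBDT, XGBoost)
are available behind the same probability interface for the comparison
experiment; they delegate to scikit-learn / xgboost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cnn_base import CNNConfig, TrainedBaseModel, default_base_configs, predict_proba, train_cnn
from .encoders import (
    AAIndexTable,
    EmbeddingTable,
    GGapConfig,
    encode_batch,
    train_word2vec,
)
from .io_formats import PeptideRecord, pad_sequence

#: Frozen meta-feature column order.
META_FEATURE_ORDER = ("onehot", "aaindex", "ggap", "word2vec")

META_ALGORITHMS = ("gnb", "lr", "adaboost", "gbdt", "xgboost")


@dataclass(frozen=True)
class Word2VecParams:
    """Embedding training settings used inside the stacking pipeline."""

    d: int = 32
    window: int = 5
    epochs: int = 100
    negative: int = 5


def _pad_records(records: Sequence[PeptideRecord]):
    return [pad_sequence(r.sequence) for r in records]


def _labels(records: Sequence[PeptideRecord]) -> np.ndarray:
    missing = [r.id for r in records if r.label is None]
    if missing:
        raise ValueError(f"unlabeled records: {missing[:5]}")
    return np.array([r.label for r in records])


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 1000003 + salt) % (2**31 - 1)


# ---------------------------------------------------------------------------
# out-of-fold meta-features


def make_meta_features(
    records: Sequence[PeptideRecord],
    base_configs: Mapping[str, CNNConfig] | None = None,
    k: int = 5,
    seed: int = 0,
    *,
    ggap_config: GGapConfig = GGapConfig(),
    aaindex_table: AAIndexTable | None = None,
    w2v: Word2VecParams = Word2VecParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold base-classifier probabilities for every sample.

    One stratified fold assignment (fixed by ``seed``) is shared across the
    four encoders so that row s of the returned n x 4 matrix concatenates
    predictions for the same held-out sample. The word2vec embedding table
    is retrained inside each fold on that fold's training split only.
    """
    records = list(records)
    y = _labels(records)
    configs = base_configs or default_base_configs(seed=seed)
    padded = _pad_records(records)

    fixed = {
        "onehot": encode_batch(padded, "onehot"),
        "aaindex": encode_batch(padded, "aaindex", aaindex_table=aaindex_table),
        "ggap": encode_batch(padded, "ggap", ggap_config=ggap_config),
    }

    n = len(records)
    meta_X = np.full((n, 4), np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        table = train_word2vec(
            [padded[i] for i in train_idx],
            d=w2v.d, window=w2v.window, epochs=w2v.epochs,
            seed=_derive_seed(seed, fold), negative=w2v.negative,
        )
        for col, encoder_id in enumerate(META_FEATURE_ORDER):
            if encoder_id == "word2vec":
                X_train = encode_batch([padded[i] for i in train_idx], "word2vec",
                                       embedding_table=table)
                X_test = encode_batch([padded[i] for i in test_idx], "word2vec",
                                      embedding_table=table)
            else:
                X_train = fixed[encoder_id][train_idx]
                X_test = fixed[encoder_id][test_idx]
            model = train_cnn(X_train, y[train_idx], configs[encoder_id])
            meta_X[test_idx, col] = predict_proba(model, X_test)
    assert not np.isnan(meta_X).any(), "fold misalignment: some sample never held out"
    return meta_X, y


# ---------------------------------------------------------------------------
# Gaussian naive Bayes (from first principles)


@dataclass(frozen=True)
class GNBParams:
    """Fitted Gaussian naive Bayes parameters for the 2-class problem."""

    class_priors: np.ndarray  # (2,), order [P(y=0), P(y=1)]
    means: np.ndarray         # (2, n_features)
    variances: np.ndarray     # (2, n_features), smoothing already added
    var_smoothing: float

    def __post_init__(self) -> None:
        if not np.isclose(self.class_priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if np.any(self.variances < self.var_smoothing * (1 - 1e-12)):
            raise ValueError("variances must be bounded below by var_smoothing")


def gnb_fit(
    meta_X: np.ndarray, y: Sequence[int] | np.ndarray, var_smoothing: float | None = None
) -> GNBParams:
    """Fit per-class feature means/variances and class priors.

    Variances use the population divisor (n_c) plus ``var_smoothing``. The
    default smoothing is 1e-9 times the largest pooled per-feature variance,
    which keeps degenerate zero-variance features finite.
    """
    meta_X = np.asarray(meta_X, dtype=float)
    y = np.asarray(y)
    if meta_X.ndim != 2 or len(meta_X) != len(y):
        raise ValueError("meta_X must be 2-D with one row per label")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    if var_smoothing is None:
        pooled_var = meta_X.var(axis=0).max()
        var_smoothing = 1e-9 * (pooled_var if pooled_var > 0 else 1.0)
    means = np.stack([meta_X[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([meta_X[y == c].var(axis=0) for c in (0, 1)]) + var_smoothing
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    return GNBParams(class_priors=priors, means=means, variances=variances,
                     var_smoothing=float(var_smoothing))


def gnb_predict_proba(params: GNBParams, x: np.ndarray) -> np.ndarray | float:
    """Posterior probability of class 1, computed in log space.

    Accepts a single feature vector or an (n, d) matrix; returns a scalar or
    an (n,) vector accordingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.means.shape[1]:
        raise ValueError("feature dimension mismatch with fitted parameters")
    log_post = np.empty((len(X), 2))
    for c in (0, 1):
        mu, var = params.means[c], params.variances[c]
        log_like = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
        log_post[:, c] = np.log(params.class_priors[c]) + log_like
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    p1 = post[:, 1] / post.sum(axis=1)
    return float(p1[0]) if single else p1


class GNBModel:
    """Thin fit/predict wrapper over the functional GNB interface."""

    def __init__(self, var_smoothing: float | None = None) -> None:
        self.var_smoothing = var_smoothing
        self.params: GNBParams | None = None

    def fit(self, X, y) -> "GNBModel":
        self.params = gnb_fit(np.asarray(X), y, self.var_smoothing)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("GNBModel is not fitted")
        p = gnb_predict_proba(self.params, np.atleast_2d(np.asarray(X, dtype=float)))
        return np.asarray(p)


class _SkMeta:
    """Uniform probability interface over delegated meta-learners."""

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def fit(self, X, y) -> "_SkMeta":
        self.estimator.fit(np.asarray(X), np.asarray(y))
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X))[:, 1]


def fit_meta(algorithm: str, meta_X: np.ndarray, y, seed: int = 0):
    """Fit the requested meta-learner on meta-features.

    ``gnb`` is the first-principles implementation above; ``lr``,
    ``adaboost`` and ``gbdt`` delegate to scikit-learn and ``xgboost`` to
    the xgboost package, all behind ``predict_proba -> P(class 1)``.
    """
    algorithm = algorithm.lower()
    if algorithm == "gnb":
        return GNBModel().fit(meta_X, y)
    if algorithm == "lr":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(random_state=seed, max_iter=1000)
    elif algorithm == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier

        est = AdaBoostClassifier(random_state=seed)
    elif algorithm == "gbdt":
        from sklearn.ensemble import GradientBoostingClassifier

        est = GradientBoostingClassifier(random_state=seed)
    elif algorithm == "xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=seed, eval_metric="logloss")
    else:
        raise ValueError(f"unknown meta algorithm {algorithm!r}; choose from {META_ALGORITHMS}")
    return _SkMeta(est).fit(meta_X, y)


# ---------------------------------------------------------------------------
# the full stacked model


@dataclass
class StackedModel:
    """Four fitted base CNNs plus the fitted meta-learner."""

    base_models: dict[str, TrainedBaseModel]
    embedding_table: EmbeddingTable
    meta: object
    meta_algorithm: str = "gnb"
    ggap_config: GGapConfig = field(default_factory=GGapConfig)
    aaindex_table: Optional[AAIndexTable] = None
    decision_threshold: float = 0.5
    meta_train_X: Optional[np.ndarray] = None
    meta_train_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if set(self.base_models) != set(META_FEATURE_ORDER):
            raise ValueError(
                f"base models must cover exactly the encoders {META_FEATURE_ORDER}"
            )


def fit_stacked(
    records: Sequence[PeptideRecord],
    base_configs: Mapping[str, CNNConfig] | None = None,
    meta_algorithm: str = "gnb",
    k: int = 5,
    seed: int = 0,
    *,
    ggap_config: GGapConfig = GGapConfig(),
    aaindex_table: AAIndexTable | None = None,
    w2v: Word2VecParams = Word2VecParams(),
) -> StackedModel:
    """Train the full stacked ensemble on labeled records.

    Meta-features are out-of-fold base predictions (k stratified folds);
    the meta-learner is fit on them; the four base models (and the word2vec
    embedding table) are then refit on the complete training set for use on
    new samples.
    """
    records = list(records)
    y = _labels(records)
    configs = base_configs or default_base_configs(seed=seed)
    meta_X, y_meta = make_meta_features(
        records, configs, k=k, seed=seed,
        ggap_config=ggap_config, aaindex_table=aaindex_table, w2v=w2v,
    )
    meta = fit_meta(meta_algorithm, meta_X, y_meta, seed=seed)

    padded = _pad_records(records)
    table = train_word2vec(
        padded, d=w2v.d, window=w2v.window, epochs=w2v.epochs,
        seed=_derive_seed(seed, 9999), negative=w2v.negative,
    )
    base_models = {}
    for encoder_id in META_FEATURE_ORDER:
        X = encode_batch(
            padded, encoder_id,
            aaindex_table=aaindex_table, ggap_config=ggap_config,
            embedding_table=table,
        )
        base_models[encoder_id] = train_cnn(X, y, configs[encoder_id])
    return StackedModel(
        base_models=base_models,
        embedding_table=table,
        meta=meta,
        meta_algorithm=meta_algorithm,
        ggap_config=ggap_config,
        aaindex_table=aaindex_table,
        meta_train_X=meta_X,
        meta_train_y=y_meta,
    )


def base_probabilities(model: StackedModel, records: Sequence[PeptideRecord]) -> np.ndarray:
    """n x 4 matrix of base-classifier probabilities in frozen column order."""
    padded = _pad_records(records)
    cols = []
    for encoder_id in META_FEATURE_ORDER:
        X = encode_batch(
            padded, encoder_id,
            aaindex_table=model.aaindex_table, ggap_config=model.ggap_config,
            embedding_table=model.embedding_table,
        )
        cols.append(predict_proba(model.base_models[encoder_id], X))
    return np.column_stack(cols)


def stacked_predict(
    model: StackedModel, records: Sequence[PeptideRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """(posterior probabilities, labels at the 0.5 threshold) per record.

    A posterior of exactly 0.5 classifies as the positive class.
    """
    meta_X = base_probabilities(model, records)
    probs = np.asarray(model.meta.predict_proba(meta_X))
    labels = (probs >= model.decision_threshold).astype(int)
    return probs, labels


def meta_feature_auc(meta_X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Univariate AUC of each meta-feature column (diagnostic)."""
    from .evaluation import auc

    return {
        name: auc(y, meta_X[:, j]) for j, name in enumerate(META_FEATURE_ORDER)
    }
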