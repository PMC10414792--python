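"""Binary-classification metrics and the k-fold cross-validation harness.

Metrics are the standard five used for peptide predictors: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/(TP+TN+FP+FN), the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the area under the ROC curve (equivalently the Mann-Whitney
probability that a random positive outscores a random negative, ties
counted one half).

Conventions: scores >= threshold predict the positive class; a zero factor
in the MCC denominator yields MCC = 0 (with a warning); an empty class
makes Sn or Sp undefined (NaN, with a warning). Cross-validation headline
numbers are unweighted fold averages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from math import sqrt
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    y: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Tally predictions (score >= threshold -> class 1) against labels."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(y) == 0:
        raise ValueError("need at least one sample")
    pred = scores >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC) from a confusion table."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if tp + fn == 0:
        warnings.warn("no positive samples: Sn undefined", RuntimeWarning)
        sn = float("nan")
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples: Sp undefined", RuntimeWarning)
        sp = float("nan")
    else:
        sp = tn / (tn + fp)
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("zero factor in MCC denominator: MCC set to 0", RuntimeWarning)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / sqrt(denom)
    return sn, sp, acc, mcc


def auc(y: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Area under the ROC curve; requires both classes present."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, scores))


@dataclass
class MetricsReport:
    """Fold-averaged Sn/Sp/Acc/MCC/AUC plus the per-fold breakdown."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    k: int = 1
    per_fold: Optional[list[dict[str, float]]] = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_scores(
        cls, y, scores, threshold: float = 0.5, k: int = 1
    ) -> "MetricsReport":
        sn, sp, acc, mcc = compute_metrics(confusion(y, scores, threshold))
        return cls(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc(y, scores), k=k)


def cross_validate(
    pipeline_factory: Callable[[], object],
    records: Sequence,
    labels: Sequence[int] | np.ndarray,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold CV of any fit/predict_proba pipeline.

    ``pipeline_factory()`` must return a fresh object with
    ``fit(records, labels)`` and ``predict_proba(records) -> scores``.
    Headline metrics are unweighted means over folds.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    records = list(records)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in skf.split(np.zeros(len(records)), labels):
        pipe = pipeline_factory()
        pipe.fit([records[i] for i in train_idx], labels[train_idx])
        scores = np.asarray(pipe.predict_proba([records[i] for i in test_idx]))
        sn, sp, acc, mcc = compute_metrics(confusion(labels[test_idx], scores, threshold))
        per_fold.append(
            {"sn": sn, "sp": sp, "acc": acc, "mcc": mcc,
             "auc": auc(labels[test_idx], scores)}
        )
    mean = {m: float(np.mean([f[m] for f in per_fold])) for m in per_fold[0]}
    return MetricsReport(k=k, per_fold=per_fold, **mean)


def roc_points(y, scores) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples for ROC export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y), np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
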