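"""Exact Shapley attribution of the meta-learner over the 4 meta-features.

With only four features the Shapley value needs no sampling: all 2^4 = 16
coalitions are enumerated exactly. The value function is interventional
(marginal replacement): v(S) is the mean model output over background rows
with the coalition features replaced by the explained point's values,

    phi_j = sum_{S subseteq F\\{j}} |S|! (|F|-|S|-1)! / |F|! * [v(S u {j}) - v(S)].

Positive phi_j pushes the posterior toward the neuropeptide class. The
exact values satisfy the efficiency (sum phi = f(x) - mean_b f(b)), dummy
and symmetry axioms to floating precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np

from .stacking import META_FEATURE_ORDER

N_FEATURES = 4


@dataclass(frozen=True)
class BackgroundSet:
    """Reference meta-feature rows defining the interventional baseline."""

    rows: np.ndarray  # (m, 4)

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[1] != N_FEATURES:
            raise ValueError(f"background must be (m, {N_FEATURES})")
        if len(self.rows) < 1:
            raise ValueError("background must contain at least one row")


@dataclass(frozen=True)
class ShapExplanation:
    """Per-feature Shapley values for one explained sample."""

    phi: np.ndarray        # (4,)
    base_value: float      # mean model output over the background
    fx: float              # model output at the explained point

    def __post_init__(self) -> None:
        if self.phi.shape != (N_FEATURES,):
            raise ValueError(f"phi must have {N_FEATURES} components")
        if abs(self.phi.sum() - (self.fx - self.base_value)) > 1e-9:
            raise ValueError("efficiency violated: sum(phi) != f(x) - base_value")


def subsample_background(
    meta_X: np.ndarray, max_rows: int = 200, seed: int = 0
) -> BackgroundSet:
    """Cap a meta-feature matrix to ``max_rows`` by seeded subsampling."""
    meta_X = np.asarray(meta_X, dtype=float)
    if len(meta_X) > max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(meta_X), size=max_rows, replace=False)
        meta_X = meta_X[np.sort(idx)]
    return BackgroundSet(rows=meta_X)


def exact_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: BackgroundSet,
) -> ShapExplanation:
    """Exact interventional Shapley values of ``f`` at ``x``.

    ``f`` maps an (n, 4) matrix to n outputs (here: the meta-learner's
    class-1 posterior). All 16 coalitions are evaluated; for each coalition
    S, v(S) averages f over background rows with the S-columns overwritten
    by x.
    """
    x = np.asarray(x, dtype=float).reshape(N_FEATURES)
    B = background.rows

    v: dict[frozenset, float] = {}
    for size in range(N_FEATURES + 1):
        for S in combinations(range(N_FEATURES), size):
            composite = B.copy()
            composite[:, list(S)] = x[list(S)]
            v[frozenset(S)] = float(np.mean(f(composite)))

    phi = np.zeros(N_FEATURES)
    for j in range(N_FEATURES):
        others = [i for i in range(N_FEATURES) if i != j]
        for size in range(N_FEATURES):
            w = factorial(size) * factorial(N_FEATURES - size - 1) / factorial(N_FEATURES)
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[j] += w * (v[fs | {j}] - v[fs])

    base_value = v[frozenset()]
    fx = float(np.mean(f(x[None, :])))
    # v(full coalition) equals f(x) exactly: every background row is fully overwritten.
    return ShapExplanation(phi=phi, base_value=base_value, fx=fx)


def explain_samples(
    f: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: BackgroundSet,
) -> list[ShapExplanation]:
    """Exact Shapley explanation for every row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return [exact_shapley(f, row, background) for row in X]


def summarize_shap(
    explanations: Sequence[ShapExplanation],
) -> tuple[dict[str, float], np.ndarray]:
    """Mean |phi| per meta-feature plus the raw per-sample phi matrix.

    The summary is the bar-chart view of feature importance: the average
    absolute Shapley value over all explained samples, keyed by encoder id
    in the frozen column order. The returned matrix (n x 4) supports
    beeswarm-style export.
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    mat = np.stack([e.phi for e in explanations])
    summary = {
        name: float(np.abs(mat[:, j]).mean()) for j, name in enumerate(META_FEATURE_ORDER)
    }
    return summary, mat
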