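"""Minimal 1-D convolutional network in numpy.

A compact, fully deterministic conv net for fixed-shape sequence feature
matrices: a stack of (conv1d -> ReLU) layers convolving along the first
axis with the second axis as input channels, a global pooling layer,
inverted dropout, one ReLU dense layer and a single sigmoid output unit,
trained with Adam on binary cross-entropy. Forward and backward passes are
written out explicitly; all randomness (initialization, batch shuffling,
dropout masks) flows from a single seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SequenceConvNet:
    """1-D conv net: (conv -> ReLU)* -> global pool -> dropout -> dense -> sigmoid.

    Parameters
    ----------
    in_len, in_ch
        Input matrix shape (sequence positions x channels).
    conv_channels, kernel_sizes
        Filter counts and (odd) kernel widths per conv layer; equal length.
    pool
        ``"max"`` (global max) or ``"mean"`` (global average) over positions,
        or ``"flatten"`` to keep the position axis (no pooling; the conv map
        is flattened into the dense layer). Flatten is the right choice when
        position carries identity rather than translation-invariant context,
        as with dipeptide-composition bins.
    dropout
        Drop probability on the pooled vector, in [0, 1).
    dense_units
        Width of the single hidden dense layer.
    seed
        Seeds weight initialization; ``fit`` reuses it for shuffling/dropout.
    """

    def __init__(
        self,
        in_len: int,
        in_ch: int,
        conv_channels: Sequence[int] = (32,),
        kernel_sizes: Sequence[int] = (5,),
        pool: str = "max",
        dropout: float = 0.5,
        dense_units: int = 64,
        seed: int = 0,
    ) -> None:
        if len(conv_channels) != len(kernel_sizes) or not conv_channels:
            raise ValueError("conv_channels and kernel_sizes must be equal-length, non-empty")
        for k in kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if pool not in ("max", "mean", "flatten"):
            raise ValueError(f"pool must be 'max', 'mean' or 'flatten', got {pool!r}")
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        length = in_len
        for k in kernel_sizes:
            length = length - k + 1
            if length < 1:
                raise ValueError("kernel stack longer than the input sequence")

        self.in_len, self.in_ch = in_len, in_ch
        self.kernel_sizes = tuple(kernel_sizes)
        self.conv_channels = tuple(conv_channels)
        self.pool = pool
        self.dropout = dropout
        self.dense_units = dense_units
        self.seed = seed

        rng = np.random.default_rng(seed)
        self.conv_W: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        ch = in_ch
        for f, k in zip(conv_channels, kernel_sizes):
            fan_in = k * ch
            self.conv_W.append(rng.normal(scale=np.sqrt(2.0 / fan_in), size=(fan_in, f)))
            self.conv_b.append(np.zeros(f))
            ch = f
        dense_in = length * ch if pool == "flatten" else ch
        self.W1 = rng.normal(scale=np.sqrt(2.0 / dense_in), size=(dense_in, dense_units))
        self.b1 = np.zeros(dense_units)
        self.W2 = rng.normal(scale=np.sqrt(2.0 / dense_units), size=(dense_units, 1))
        self.b2 = np.zeros(1)

        self._adam_state: dict | None = None

    # -- parameter plumbing -------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        return [*self.conv_W, *self.conv_b, self.W1, self.b1, self.W2, self.b2]

    def _set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.conv_W)
        self.conv_W = params[:n]
        self.conv_b = params[n:2 * n]
        self.W1, self.b1, self.W2, self.b2 = params[2 * n:]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        current = self._params()
        if len(weights) != len(current):
            raise ValueError("weight list length mismatch")
        for got, ref in zip(weights, current):
            if np.asarray(got).shape != ref.shape:
                raise ValueError("weight shape mismatch")
        self._set_params([np.asarray(w, dtype=float).copy() for w in weights])

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool, rng: np.random.Generator | None):
        cache: dict = {"conv": []}
        A = X
        for W, b, k in zip(self.conv_W, self.conv_b, self.kernel_sizes):
            win = sliding_window_view(A, k, axis=1)          # (n, P, C, k)
            win = win.transpose(0, 1, 3, 2)                  # (n, P, k, C)
            n, P = win.shape[0], win.shape[1]
            flat = win.reshape(n, P, -1)                     # (n, P, k*C)
            Z = flat @ W + b
            out = np.maximum(Z, 0.0)
            cache["conv"].append((flat, Z, A.shape, k))
            A = out
        if self.pool == "max":
            arg = A.argmax(axis=1)                           # (n, F)
            M = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
            cache["pool"] = (arg, A.shape)
        elif self.pool == "mean":
            M = A.mean(axis=1)
            cache["pool"] = (None, A.shape)
        else:  # flatten
            M = A.reshape(A.shape[0], -1)
            cache["pool"] = (None, A.shape)
        if train and self.dropout > 0:
            mask = (rng.random(M.shape) >= self.dropout) / (1.0 - self.dropout)
            M = M * mask
            cache["drop"] = mask
        else:
            cache["drop"] = None
        cache["M"] = M
        H = np.maximum(M @ self.W1 + self.b1, 0.0)
        cache["H"] = H
        logit = (H @ self.W2 + self.b2)[:, 0]
        p = _sigmoid(logit)
        return p, cache

    def _backward(self, p: np.ndarray, y: np.ndarray, cache: dict) -> list[np.ndarray]:
        n = len(y)
        dlogit = (p - y) / n                                  # (n,)
        H, M = cache["H"], cache["M"]
        dW2 = H.T @ dlogit[:, None]
        db2 = np.array([dlogit.sum()])
        dH = dlogit[:, None] @ self.W2.T
        dH[H <= 0] = 0.0
        dW1 = M.T @ dH
        db1 = dH.sum(axis=0)
        dM = dH @ self.W1.T
        if cache["drop"] is not None:
            dM = dM * cache["drop"]
        arg, conv_shape = cache["pool"]
        if self.pool == "max":
            dA = np.zeros(conv_shape)
            n_idx = np.arange(conv_shape[0])[:, None]
            f_idx = np.arange(conv_shape[2])[None, :]
            dA[n_idx, arg, f_idx] = dM
        elif self.pool == "mean":
            dA = np.broadcast_to(dM[:, None, :] / conv_shape[1], conv_shape).copy()
        else:  # flatten
            dA = dM.reshape(conv_shape)

        d_conv_W: list[np.ndarray] = []
        d_conv_b: list[np.ndarray] = []
        for (flat, Z, in_shape, k), W in zip(reversed(cache["conv"]), reversed(self.conv_W)):
            dZ = dA * (Z > 0)
            nb, P, F = dZ.shape
            dW = flat.reshape(nb * P, -1).T @ dZ.reshape(nb * P, F)
            db = dZ.sum(axis=(0, 1))
            d_conv_W.append(dW)
            d_conv_b.append(db)
            dflat = dZ @ W.T                                  # (n, P, k*C)
            C = in_shape[2]
            dwin = dflat.reshape(nb, P, k, C)
            dA = np.zeros(in_shape)
            for j in range(k):
                dA[:, j:j + P, :] += dwin[:, :, j, :]
        d_conv_W.reverse()
        d_conv_b.reverse()
        return [*d_conv_W, *d_conv_b, dW1, db1, dW2, db2]

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        seed: int | None = None,
    ) -> list[float]:
        """Train with Adam on binary cross-entropy; returns per-epoch losses."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.in_len, self.in_ch):
            raise ValueError(f"X must have shape (n, {self.in_len}, {self.in_ch})")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        losses = []
        n = len(y)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                p, cache = self._forward(X[idx], train=True, rng=rng)
                p_c = np.clip(p, 1e-12, 1 - 1e-12)
                epoch_loss += float(
                    -(y[idx] * np.log(p_c) + (1 - y[idx]) * np.log(1 - p_c)).sum()
                )
                grads = self._backward(p, y[idx], cache)
                t += 1
                params = self._params()
                for j, (param, g) in enumerate(zip(params, grads)):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    param -= learning_rate * (m[j] / (1 - b1**t)) / (
                        np.sqrt(v[j] / (1 - b2**t)) + eps
                    )
            losses.append(epoch_loss / n)
        return losses

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each input matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.in_len, self.in_ch):
            raise ValueError(f"X must have shape (n, {self.in_len}, {self.in_ch})")
        p, _ = self._forward(X, train=False, rng=None)
        return p
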