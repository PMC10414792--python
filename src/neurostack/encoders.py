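"""Four numeric encodings of a length-100 padded peptide.

Every encoder consumes a :class:`~neurostack.io_formats.PaddedSequence` and
emits a fixed-shape matrix:

==========  =========  ==============================================
encoder id  shape      row semantics
==========  =========  ==============================================
onehot      100 x 20   basis vector of the residue; pad rows = 0.05
aaindex     100 x 14   14 physicochemical property values
ggap        440 x 10   one-hot of the (capped) g-gap dipeptide count
word2vec    100 x d    skip-gram embedding vector of the residue
==========  =========  ==============================================

The pad residue 'B' one-hot encodes as the constant 0.05 vector (a uniform
residue-frequency prior: 20 x 0.05 = 1), and under AAIndex as the
per-property mean over the 20 natural residues.

The g-gap dipeptide space is the 21 x 21 ordered pairs over the padded
alphabet minus the pure-pad pair (B,B): 441 - 1 = 440 bins. Counts are
clipped at 10 and expressed as a 10-dimensional one-hot per bin (count 0 is
the all-zero row).

Alphabet order is frozen as A,C,D,...,Y then B last; all index mappings in
the package use it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._aaindex_data import AAINDEX_ACCESSIONS, AAINDEX_PROPERTIES
from .io_formats import AA_ALPHABET, PAD_CHAR, PAD_LEN, PaddedSequence

#: 21-letter alphabet: the 20 natural residues then the pad letter.
ALPHABET21 = AA_ALPHABET + PAD_CHAR

_IDX20 = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_IDX21 = {aa: i for i, aa in enumerate(ALPHABET21)}

ENCODER_IDS = ("onehot", "aaindex", "ggap", "word2vec")

#: Number of g-gap dipeptide bins: 21*21 ordered pairs minus (B,B).
N_GGAP_BINS = 21 * 21 - 1


@dataclass(frozen=True)
class EncodedMatrix:
    """A numeric feature matrix tagged with the encoder that produced it."""

    values: np.ndarray
    encoder_id: str

    def __post_init__(self) -> None:
        if self.encoder_id not in ENCODER_IDS:
            raise ValueError(f"unknown encoder id {self.encoder_id!r}")
        if self.values.ndim != 2:
            raise ValueError("encoded values must be a 2-D matrix")
        expected_rows = {"onehot": PAD_LEN, "aaindex": PAD_LEN,
                         "ggap": N_GGAP_BINS, "word2vec": PAD_LEN}[self.encoder_id]
        expected_cols = {"onehot": 20, "aaindex": 14, "ggap": 10}.get(self.encoder_id)
        if self.values.shape[0] != expected_rows:
            raise ValueError(
                f"{self.encoder_id}: expected {expected_rows} rows, got {self.values.shape[0]}"
            )
        if expected_cols is not None and self.values.shape[1] != expected_cols:
            raise ValueError(
                f"{self.encoder_id}: expected {expected_cols} cols, got {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.encoder_id}: non-finite values in encoding")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# one-hot


def encode_onehot(padded: PaddedSequence) -> EncodedMatrix:
    """Positional one-hot encoding; pad rows are the uniform 0.05 vector."""
    mat = np.zeros((PAD_LEN, 20))
    for i, aa in enumerate(padded.residues):
        if aa == PAD_CHAR:
            mat[i, :] = 0.05
        else:
            mat[i, _IDX20[aa]] = 1.0
    return EncodedMatrix(mat, "onehot")


# ---------------------------------------------------------------------------
# AAIndex


@dataclass(frozen=True)
class AAIndexTable:
    """A residue-by-property matrix addressed by AAIndex accession ids."""

    accession_ids: tuple[str, ...]
    values: np.ndarray  # 20 x n_properties, residue order = AA_ALPHABET

    def __post_init__(self) -> None:
        if self.values.shape != (20, len(self.accession_ids)):
            raise ValueError(
                f"table shape {self.values.shape} does not match "
                f"20 residues x {len(self.accession_ids)} accessions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AAIndex table contains non-finite values")

    @property
    def n_properties(self) -> int:
        return len(self.accession_ids)

    @property
    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def default_aaindex_table() -> AAIndexTable:
    """The vendored 14-property table (see ``_aaindex_data``)."""
    values = np.array(
        [[AAINDEX_PROPERTIES[acc][aa] for acc in AAINDEX_ACCESSIONS] for aa in AA_ALPHABET]
    )
    return AAIndexTable(accession_ids=AAINDEX_ACCESSIONS, values=values)


_DEFAULT_TABLE = default_aaindex_table()


def encode_aaindex(padded: PaddedSequence, table: AAIndexTable | None = None) -> EncodedMatrix:
    """Row i = property values of residue i; pad rows = per-property means.

    The mean-row convention for 'B' mirrors the uniform-frequency reading of
    the one-hot pad vector: the pad carries the average residue, not any
    particular one.
    """
    table = table if table is not None else _DEFAULT_TABLE
    if table.n_properties != 14:
        raise ValueError(f"expected 14 AAIndex properties, got {table.n_properties}")
    mean_row = table.column_means
    mat = np.empty((PAD_LEN, table.n_properties))
    for i, aa in enumerate(padded.residues):
        mat[i] = mean_row if aa == PAD_CHAR else table.values[_IDX20[aa]]
    return EncodedMatrix(mat, "aaindex")


# ---------------------------------------------------------------------------
# g-gap dipeptides


@dataclass(frozen=True)
class GGapConfig:
    """Gap width g (ordered pairs s[i], s[i+g+1]) and the count clip cap."""

    g: int = 0
    count_cap: int = 10

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if PAD_LEN - self.g - 1 < 1:
            raise ValueError(f"g={self.g} leaves no valid pair in a length-{PAD_LEN} sequence")
        if self.count_cap < 1:
            raise ValueError("count_cap must be >= 1")


def ggap_bin_index(a: str, b: str) -> int:
    """Bin index of the ordered pair (a, b) in the 440-bin dipeptide space.

    Pairs are enumerated row-major over the 21-letter alphabet (A..Y, B);
    (B,B) would be the final index 440 and is excluded.
    """
    idx = _IDX21[a] * 21 + _IDX21[b]
    if idx == N_GGAP_BINS:  # (B,B)
        raise ValueError("the pure-pad pair (B,B) has no bin")
    return idx


def count_ggap_pairs(padded: PaddedSequence, config: GGapConfig = GGapConfig()) -> np.ndarray:
    """Tally g-gap dipeptides over the padded sequence into 440 bins.

    (B,B) pairs (both members in the pad suffix) are discarded; pairs with a
    single 'B' member are retained, which is what makes the B-containing
    bins meaningful.
    """
    s = padded.residues
    counts = np.zeros(N_GGAP_BINS, dtype=np.int64)
    step = config.g + 1
    for i in range(PAD_LEN - step):
        a, b = s[i], s[i + step]
        if a == PAD_CHAR and b == PAD_CHAR:
            continue
        counts[ggap_bin_index(a, b)] += 1
    return counts


def encode_ggap(padded: PaddedSequence, config: GGapConfig = GGapConfig()) -> EncodedMatrix:
    """One-hot the per-bin counts into a 440 x 10 matrix.

    Count c in 1..cap sets column c-1; count 0 leaves an all-zero row;
    counts above the cap clip to the cap (column cap-1).
    """
    counts = count_ggap_pairs(padded, config)
    mat = np.zeros((N_GGAP_BINS, config.count_cap))
    clipped = np.minimum(counts, config.count_cap)
    nonzero = clipped > 0
    mat[np.nonzero(nonzero)[0], clipped[nonzero] - 1] = 1.0
    return EncodedMatrix(mat, "ggap")


# ---------------------------------------------------------------------------
# word2vec (skip-gram)


@dataclass(frozen=True)
class EmbeddingTable:
    """Per-residue embedding vectors plus the training configuration."""

    token_vectors: Mapping[str, np.ndarray]
    d: int
    training_params: tuple = ()

    def __post_init__(self) -> None:
        missing = [t for t in ALPHABET21 if t not in self.token_vectors]
        if missing:
            raise ValueError(f"embedding table missing tokens: {missing}")
        for t, v in self.token_vectors.items():
            if np.asarray(v).shape != (self.d,):
                raise ValueError(f"token {t!r}: vector dimension != {self.d}")

    def matrix(self) -> np.ndarray:
        """21 x d matrix in frozen alphabet order."""
        return np.stack([np.asarray(self.token_vectors[t]) for t in ALPHABET21])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_word2vec(
    corpus: Sequence[PaddedSequence],
    d: int = 32,
    window: int = 5,
    epochs: int = 100,
    seed: int = 0,
    algorithm: str = "skip-gram",
    negative: int = 5,
) -> EmbeddingTable:
    """Train skip-gram residue embeddings with negative sampling.

    Residues are the word tokens (vocabulary = the 21-letter padded
    alphabet). Because the vocabulary is tiny, the skip-gram
    negative-sampling objective is optimized in its exact expectation:
    center-context pairs are aggregated into a 21 x 21 co-occurrence count
    matrix and the expected negative term is taken over the unigram^0.75
    noise distribution, so each epoch is one full-batch gradient step. This
    is the same objective SGD-based trainers approximate by sampling, made
    deterministic for a fixed seed.

    Tokens absent from the corpus keep the zero vector.
    """
    if algorithm != "skip-gram":
        raise NotImplementedError(
            "only skip-gram is supported; CBOW was considered and discarded upstream"
        )
    if not corpus:
        raise ValueError("empty corpus")
    if window < 1 or epochs < 1 or d < 1:
        raise ValueError("d, window and epochs must be >= 1")

    V = len(ALPHABET21)
    cooc = np.zeros((V, V))
    unigram = np.zeros(V)
    for padded in corpus:
        idx = np.array([_IDX21[c] for c in padded.residues])
        unigram += np.bincount(idx, minlength=V)
        n = len(idx)
        for off in range(1, window + 1):
            centers, contexts = idx[:-off], idx[off:]
            np.add.at(cooc, (centers, contexts), 1.0)
            np.add.at(cooc, (contexts, centers), 1.0)

    present = unigram > 0
    noise = np.where(present, unigram, 0.0) ** 0.75
    noise /= noise.sum()
    total_pairs = cooc.sum()
    row_counts = cooc.sum(axis=1)

    rng = np.random.default_rng(seed)
    v_in = rng.normal(scale=0.1, size=(V, d))
    v_out = rng.normal(scale=0.1, size=(V, d))
    v_in[~present] = 0.0
    v_out[~present] = 0.0

    # Adam, full-batch; loss normalized by the total pair count.
    lr, b1, b2, eps = 0.05, 0.9, 0.999, 1e-8
    m = [np.zeros_like(v_in), np.zeros_like(v_out)]
    u = [np.zeros_like(v_in), np.zeros_like(v_out)]
    neg_weight = negative * np.outer(row_counts, noise)
    for t in range(1, epochs + 1):
        scores = v_in @ v_out.T
        # dL/dscore for L = -sum cooc*log sig(s) - sum neg_weight*log sig(-s)
        g_score = (-cooc * _sigmoid(-scores) + neg_weight * _sigmoid(scores)) / total_pairs
        grads = [g_score @ v_out, g_score.T @ v_in]
        for j, (param, g) in enumerate(zip((v_in, v_out), grads)):
            m[j] = b1 * m[j] + (1 - b1) * g
            u[j] = b2 * u[j] + (1 - b2) * g * g
            param -= lr * (m[j] / (1 - b1**t)) / (np.sqrt(u[j] / (1 - b2**t)) + eps)
        v_in[~present] = 0.0
        v_out[~present] = 0.0

    vectors = {t: v_in[i].copy() for t, i in _IDX21.items()}
    params = (("window", window), ("epochs", epochs), ("seed", seed),
              ("algorithm", algorithm), ("negative", negative))
    return EmbeddingTable(token_vectors=vectors, d=d, training_params=params)


def encode_word2vec(padded: PaddedSequence, table: EmbeddingTable) -> EncodedMatrix:
    """Row i = embedding vector of residue i (shape 100 x d)."""
    try:
        mat = np.stack([np.asarray(table.token_vectors[aa]) for aa in padded.residues])
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from embedding table") from exc
    return EncodedMatrix(mat, "word2vec")


# ---------------------------------------------------------------------------
# convenience


def encode_batch(
    padded_seqs: Iterable[PaddedSequence],
    encoder_id: str,
    *,
    aaindex_table: AAIndexTable | None = None,
    ggap_config: GGapConfig | None = None,
    embedding_table: EmbeddingTable | None = None,
) -> np.ndarray:
    """Encode many sequences into one (n, rows, cols) array."""
    if encoder_id == "onehot":
        mats = [encode_onehot(p).values for p in padded_seqs]
    elif encoder_id == "aaindex":
        mats = [encode_aaindex(p, aaindex_table).values for p in padded_seqs]
    elif encoder_id == "ggap":
        cfg = ggap_config or GGapConfig()
        mats = [encode_ggap(p, cfg).values for p in padded_seqs]
    elif encoder_id == "word2vec":
        if embedding_table is None:
            raise ValueError("word2vec encoding requires a trained EmbeddingTable")
        mats = [encode_word2vec(p, embedding_table).values for p in padded_seqs]
    else:
        raise ValueError(f"unknown encoder id {encoder_id!r}")
    return np.stack(mats)
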