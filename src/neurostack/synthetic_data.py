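"""Synthetic labeled peptide datasets with a plantable class signal.

Real neuropeptide benchmarks pair curated neuropeptides with length-matched
Swiss-Prot decoys; neither is bundled here. This module emulates the
statistical shape of such a benchmark: balanced two-class sets of
variable-length peptides (5-100 aa) drawn from a background residue
frequency model, where positives carry a planted sequence motif of
controllable strength. A perfectly class-predictive motif gives every
pipeline stage a known oracle; motif_rate < 1 or a motif of length 0
weakens or removes the signal.

The generator supplies statistical structure only — it does not simulate
neuropeptide biology (cleavage sites, precursor context, homology).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import AA_ALPHABET, PeptideRecord

#: Approximate Swiss-Prot residue frequencies (fractions, order AA_ALPHABET),
#: for callers who want a protein-like rather than uniform background.
SWISSPROT_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0228, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic benchmark draw."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (5, 100)
    motif: str = "WKRFC"
    motif_rate: float = 1.0
    background_freqs: Optional[np.ndarray] = None  # 20 probs, order AA_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        if len(self.motif) > lo:
            raise ValueError(
                f"motif length {len(self.motif)} exceeds minimum sequence length {lo}"
            )
        bad = set(self.motif) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"motif contains invalid residues {sorted(bad)}")
        if not 0 <= self.motif_rate <= 1:
            raise ValueError("motif_rate must be in [0, 1]")
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs, dtype=float)
            if f.shape != (20,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("background_freqs must be 20 probabilities summing to 1")

    @property
    def freqs(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(20, 1 / 20)
        return np.asarray(self.background_freqs, dtype=float)


def generate_dataset(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Draw a labeled peptide set; deterministic for a fixed spec + seed.

    Negatives are i.i.d. draws from the background model with lengths
    uniform over ``length_range``. Positives are drawn the same way and then,
    with probability ``motif_rate``, have the motif overwritten at a uniform
    random valid position (overwriting keeps lengths untouched). Ids encode
    class and index (``pos_0001`` / ``neg_0001``).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    alphabet = np.array(list(AA_ALPHABET))
    records: list[PeptideRecord] = []

    def draw(length: int) -> list[str]:
        return list(alphabet[rng.choice(20, size=length, p=spec.freqs)])

    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        chars = draw(length)
        if spec.motif and rng.random() < spec.motif_rate:
            start = int(rng.integers(0, length - len(spec.motif) + 1))
            chars[start:start + len(spec.motif)] = list(spec.motif)
        records.append(PeptideRecord(f"pos_{i+1:04d}", "".join(chars), 1))
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        records.append(PeptideRecord(f"neg_{i+1:04d}", "".join(draw(length)), 0))
    return records


def generate_meta_features(
    n: int,
    separation: float,
    seed: int = 0,
    informative: Sequence[int] = (0, 1, 2, 3),
    noise_sd: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct synthetic meta-features: class-conditional Gaussians in [0,1]^4.

    Informative columns have class means 0.5 -/+ separation/2 (class 0 low,
    class 1 high); non-informative columns are centered at 0.5 for both
    classes. Values are clipped to [0, 1]; labels are balanced (class sizes
    differ by at most one when n is odd).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    n1 = n // 2
    n0 = n - n1
    y = np.array([0] * n0 + [1] * n1)
    means = np.full((n, 4), 0.5)
    for j in informative:
        means[y == 0, j] = 0.5 - separation / 2
        means[y == 1, j] = 0.5 + separation / 2
    X = np.clip(means + rng.normal(scale=noise_sd, size=(n, 4)), 0.0, 1.0)
    perm = rng.permutation(n)
    return X[perm], y[perm]
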