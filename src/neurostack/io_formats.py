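"""Peptide dataset I/O: FASTA reading/writing, length filtering, padding, splitting.

Peptides are short (5-100 residue) sequences over the 20 natural amino
acids. For fixed-size encoder input every sequence is right-padded with the
pseudo-residue ``B`` to a common length of 100.

Labels (1 = neuropeptide, 0 = non-neuropeptide) travel either in the FASTA
header as a ``|label=`` suffix (``>pep_1|label=1``) or in a companion
two-column TSV ``id<TAB>label``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

#: The 20 natural amino acids in fixed alphabetical order. This ordering is
#: frozen: every index-based encoding in the package refers to it.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Pseudo-residue used for right padding.
PAD_CHAR = "B"

#: Fixed model input length; shorter peptides are padded up to it.
PAD_LEN = 100

_AA_SET = frozenset(AA_ALPHABET)


class FastaParseError(ValueError):
    """Structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """A record whose sequence leaves the 20-letter amino-acid alphabet."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identifier, residue string, optional binary label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residue(s) "
                f"{''.join(sorted(bad))!r} (allowed: {AA_ALPHABET})"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PaddedSequence:
    """A peptide right-padded with 'B' to exactly ``PAD_LEN`` residues."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != PAD_LEN:
            raise ValueError(f"padded length must be {PAD_LEN}, got {len(self.residues)}")
        core = self.residues.rstrip(PAD_CHAR)
        if PAD_CHAR in core:
            raise ValueError("'B' padding must be a contiguous suffix")
        bad = set(core) - _AA_SET
        if bad:
            raise ValueError(f"invalid residues in padded sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return PAD_LEN

    @property
    def unpadded(self) -> str:
        return self.residues.rstrip(PAD_CHAR)


@dataclass(frozen=True)
class DatasetSplit:
    """A stratified train/test partition of labeled records."""

    train: tuple[PeptideRecord, ...]
    test: tuple[PeptideRecord, ...]
    seed: int


def _parse_header(header: str) -> tuple[str, Optional[int]]:
    """Split a FASTA id token into (record id, optional label).

    The convention is ``id|label=0`` / ``id|label=1``; any other ``|`` fields
    are treated as part of the id.
    """
    if "|label=" in header:
        rid, _, raw = header.rpartition("|label=")
        try:
            label = int(raw)
        except ValueError as exc:
            raise FastaParseError(f"header {header!r}: label must be 0 or 1") from exc
        if label not in (0, 1):
            raise FastaParseError(f"header {header!r}: label must be 0 or 1")
        return rid, label
    return header, None


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptides from a FASTA file.

    Sequences are uppercased before validation; any residue outside the
    20-letter alphabet (including the pad letter B, ambiguity codes J/O/U/X/Z
    and the stop character ``*``) raises :class:`SequenceValidationError`
    naming the offending record.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path.name}: line {lineno}: expected a '>' header before sequence data"
            )
        break
    else:
        raise FastaParseError(f"{path.name}: no FASTA records found")

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        rid, label = _parse_header(entry.id)
        seq = str(entry.seq).upper()
        rec = PeptideRecord(id=rid, sequence=seq, label=label)
        if rec.id in seen:
            raise FastaParseError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    return records


def read_fasta_lenient(path: str | Path) -> tuple[list[PeptideRecord], dict[str, str]]:
    """Like :func:`read_fasta`, but collects per-record validation failures.

    Returns (valid records, {record id: error message}); structural FASTA
    errors (no header, duplicate id) still raise.
    """
    path = Path(path)
    text = path.read_text()
    records: list[PeptideRecord] = []
    errors: dict[str, str] = {}
    seen: set[str] = set()
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        try:
            rid, label = _parse_header(entry.id)
        except FastaParseError as exc:
            errors[entry.id] = str(exc)
            continue
        if rid in seen:
            raise FastaParseError(f"{path.name}: duplicate record id {rid!r}")
        seen.add(rid)
        try:
            records.append(PeptideRecord(id=rid, sequence=str(entry.seq).upper(), label=label))
        except (SequenceValidationError, ValueError) as exc:
            errors[rid] = str(exc)
    if not records and not errors:
        raise FastaParseError(f"{path.name}: no FASTA records found")
    return records, errors


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records to FASTA, embedding labels as ``|label=`` header suffixes."""
    out = []
    for rec in records:
        rid = rec.id if rec.label is None else f"{rec.id}|label={rec.label}"
        out.append(SeqRecord(Seq(rec.sequence), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (id, label) into a mapping."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"label TSV line {lineno}: expected 2 tab-separated fields")
        rid, raw = parts
        if raw not in ("0", "1"):
            raise ValueError(f"label TSV line {lineno}: label must be 0 or 1, got {raw!r}")
        labels[rid] = int(raw)
    return labels


def attach_labels(records: Sequence[PeptideRecord], labels: dict[str, int]) -> list[PeptideRecord]:
    """Return records with labels taken from ``labels`` (overriding header labels)."""
    out = []
    for rec in records:
        if rec.id in labels:
            out.append(PeptideRecord(rec.id, rec.sequence, labels[rec.id]))
        else:
            out.append(rec)
    return out


def filter_by_length(
    records: Sequence[PeptideRecord], min_len: int = 5, max_len: int = PAD_LEN
) -> list[PeptideRecord]:
    """Keep records with min_len <= length <= max_len (both bounds inclusive).

    The defaults drop sequences shorter than 5 or longer than 100 residues,
    the working definition of a peptide in this package.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    return [r for r in records if min_len <= len(r) <= max_len]


def pad_sequence(sequence: str, target_len: int = PAD_LEN) -> PaddedSequence:
    """Right-pad a residue string with 'B' to ``target_len``."""
    if len(sequence) > target_len:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds target length {target_len}"
        )
    if not sequence:
        raise ValueError("cannot pad an empty sequence")
    return PaddedSequence(sequence + PAD_CHAR * (target_len - len(sequence)))


def split_train_test(
    records: Sequence[PeptideRecord], test_fraction: float = 0.2, *, seed: int
) -> DatasetSplit:
    """Stratified train/test split, deterministic for a fixed seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    unlabeled = [r.id for r in records if r.label is None]
    if unlabeled:
        raise ValueError(f"cannot split unlabeled records: {unlabeled[:5]}")
    labels = [r.label for r in records]
    train, test = train_test_split(
        list(records),
        test_size=test_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return DatasetSplit(train=tuple(train), test=tuple(test), seed=seed)
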