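"""Amino-acid alphabets, sequence encodings and the text formats the tool touches.

Two encodings live here:

* the extended-alphabet integer encoding used by the embedding-based network:
  26 residue codes (the 20 standard amino acids plus the ambiguity/rare codes
  B, J, O, U, X, Z) indexed 1..26 in alphabetical order, with index 0 reserved
  for padding;
* the pseudo one-hot encoding used by the fixed-length baseline: 20 standard
  residues plus X one-hot in 21 dimensions, with the ambiguity codes B, J, Z
  interpolating between their two manifestations (e.g. J = 1/2 I + 1/2 L).

File formats: FASTA for sequences (via Biopython), tab-separated tables for
labels (id, group_id) and predictions (id, group, confidence, model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Extended IUPAC protein codes: the 20 standard residues plus B, J, O, U, X, Z.
EXTENDED_RESIDUES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Column order of the 21-dimensional baseline encoding: standard residues then X.
BASELINE_RESIDUES = STANDARD_RESIDUES + "X"

PADDING_INDEX = 0

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlphabetSpec:
    """An ordered residue alphabet with 1-based integer indices.

    Index 0 is reserved for padding and never denotes a residue.
    ``ambiguity_table`` maps an ambiguous symbol to ``[(symbol, weight), ...]``
    pairs whose weights sum to 1; it is empty for the extended alphabet, where
    every code gets its own embedding vector.
    """

    symbols: tuple[str, ...]
    index_of: dict[str, int]
    padding_index: int = PADDING_INDEX
    ambiguity_table: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def symbol_of(self, index: int) -> str:
        if index == self.padding_index:
            raise ValueError("index 0 is the padding sentinel, not a residue")
        return self.symbols[index - 1]


def build_extended_alphabet() -> AlphabetSpec:
    """The 26-letter extended alphabet with alphabetical indices 1..26."""
    symbols = tuple(EXTENDED_RESIDUES)
    return AlphabetSpec(
        symbols=symbols,
        index_of={s: i + 1 for i, s in enumerate(symbols)},
    )


#: Ambiguity interpolation of the baseline encoding. B/J/Z split half/half over
#: their manifestations; the rare codes O and U carry no column and fold into X.
BASELINE_AMBIGUITY: dict[str, tuple[tuple[str, float], ...]] = {
    "B": (("D", 0.5), ("N", 0.5)),
    "J": (("I", 0.5), ("L", 0.5)),
    "Z": (("E", 0.5), ("Q", 0.5)),
}


def build_baseline_alphabet() -> AlphabetSpec:
    """The 21-letter baseline alphabet (standard residues + X) with ambiguity rows."""
    symbols = tuple(BASELINE_RESIDUES)
    return AlphabetSpec(
        symbols=symbols,
        index_of={s: i + 1 for i, s in enumerate(symbols)},
        ambiguity_table=dict(BASELINE_AMBIGUITY),
    )


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: id (first header token), free-text description, residues."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class EncodedSequence:
    indices: np.ndarray  # 1-based residue indices, dtype int
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("encoded sequence must contain at least one residue")


@dataclass(frozen=True)
class EncodedBatch:
    """Right-padded integer matrix (batch x L_max) plus the true lengths."""

    matrix: np.ndarray
    lengths: np.ndarray


@dataclass(frozen=True)
class GroupLabelMap:
    """Bijection between group identifier strings and contiguous 0-based indices."""

    group_ids: tuple[str, ...]
    index_of: dict[str, int]

    @classmethod
    def from_groups(cls, groups: Iterable[str]) -> "GroupLabelMap":
        """Build from group ids; order = sorted unique, so the map is reproducible."""
        unique = sorted(set(groups))
        return cls(group_ids=tuple(unique), index_of={g: i for i, g in enumerate(unique)})

    def __len__(self) -> int:
        return len(self.group_ids)


class EmptySequenceError(ValueError):
    """A record's residue string is empty (in the file, or after sanitation)."""


class SequenceTooLongError(ValueError):
    """A sequence exceeds the fixed input length of the baseline encoding."""


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Stream records from a FASTA file in file order.

    Line-wrapped sequences are concatenated. A record with an empty sequence is
    an error naming the record; an entirely empty file yields an empty stream
    with a warning.
    """
    path = Path(path)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise EmptySequenceError(f"record '{rec.id}' in {path} has an empty sequence")
        n += 1
        yield ProteinRecord(id=rec.id, description=rec.description, sequence=seq)
    if n == 0:
        logger.warning("no FASTA records found in %s", path)


def sanitize_sequence(record_id: str, sequence: str, symbols: Sequence[str]) -> str:
    """Uppercase, strip one trailing stop '*', map anything else foreign to 'X'."""
    seq = sequence.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
        logger.warning("stripped trailing stop '*' from sequence '%s'", record_id)
    known = set(symbols)
    if not set(seq) <= known:
        cleaned = []
        for ch in seq:
            if ch in known:
                cleaned.append(ch)
            else:
                cleaned.append("X")
                logger.warning(
                    "replaced unknown character %r with 'X' in sequence '%s'", ch, record_id
                )
        seq = "".join(cleaned)
    if not seq:
        raise EmptySequenceError(f"sequence '{record_id}' is empty after sanitation")
    return seq


def encode_sequence(record: ProteinRecord, alphabet: AlphabetSpec) -> EncodedSequence:
    """Sanitize and translate a record into 1-based alphabet indices."""
    seq = sanitize_sequence(record.id, record.sequence, alphabet.symbols)
    idx = np.fromiter((alphabet.index_of[c] for c in seq), dtype=np.int64, count=len(seq))
    return EncodedSequence(indices=idx, length=len(seq))


def decode_indices(indices: np.ndarray, alphabet: AlphabetSpec) -> str:
    """Inverse of :func:`encode_sequence` on sanitized sequences."""
    return "".join(alphabet.symbol_of(int(i)) for i in indices)


def pad_and_batch(seqs: list[EncodedSequence], min_length: int = 36) -> EncodedBatch:
    """Right-pad sequences with the padding index into one matrix.

    ``min_length`` defaults to the largest convolution filter size (36), so that
    even a single-residue input offers at least one valid window to every filter.
    """
    if not seqs:
        raise ValueError("cannot batch an empty list of sequences")
    lengths = np.array([s.length for s in seqs], dtype=np.int64)
    l_max = max(int(lengths.max()), min_length)
    matrix = np.full((len(seqs), l_max), PADDING_INDEX, dtype=np.int64)
    for i, s in enumerate(seqs):
        matrix[i, : s.length] = s.indices
    return EncodedBatch(matrix=matrix, lengths=lengths)


def encode_pseudo_onehot(record: ProteinRecord, fixed_length: int = 1000) -> np.ndarray:
    """Fixed-length pseudo one-hot matrix (fixed_length x 21) for the baseline.

    Standard residues and X are one-hot; B, J, Z put weight 1/2 on each of their
    two manifestations; O and U fold into X. Rows past the sequence end are zero.
    Sequences longer than ``fixed_length`` are rejected (the baseline discards
    them), raising :class:`SequenceTooLongError`.
    """
    alphabet = build_baseline_alphabet()
    # Sanitize against the extended code set first so B/J/Z survive to interpolate.
    seq = sanitize_sequence(record.id, record.sequence, EXTENDED_RESIDUES)
    if len(seq) > fixed_length:
        logger.warning(
            "sequence '%s' has length %d > fixed length %d; record rejected",
            record.id, len(seq), fixed_length,
        )
        raise SequenceTooLongError(
            f"sequence '{record.id}' (length {len(seq)}) exceeds fixed length {fixed_length}"
        )
    out = np.zeros((fixed_length, alphabet.size), dtype=np.float32)
    col = {s: i for i, s in enumerate(alphabet.symbols)}
    for pos, ch in enumerate(seq):
        if ch in alphabet.ambiguity_table:
            for sym, w in alphabet.ambiguity_table[ch]:
                out[pos, col[sym]] = w
        elif ch in col:
            out[pos, col[ch]] = 1.0
        else:  # O, U and any other foreign extended code carry no column
            out[pos, col["X"]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Label and prediction tables
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["id", "group_id"]
PREDICTION_COLUMNS = ["id", "group", "confidence", "model"]


def read_labels(path: str | Path, fasta_ids: set[str] | None = None) -> dict[str, str]:
    """Read a two-column (id, group_id) TSV with header into an ordered mapping.

    Duplicate sequence ids are an error. If ``fasta_ids`` is given, label ids
    absent from it draw a warning (but are kept).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != LABEL_COLUMNS:
        raise ValueError(f"label table {path} must have columns {LABEL_COLUMNS}, got {list(df.columns)}")
    dupes = df["id"][df["id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate sequence id(s) in {path}: {sorted(set(dupes))}")
    if fasta_ids is not None:
        missing = [i for i in df["id"] if i not in fasta_ids]
        for i in missing:
            logger.warning("label id '%s' not present in the FASTA input", i)
    return dict(zip(df["id"], df["group_id"]))


def write_labels(labels: Iterable[tuple[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(list(labels), columns=LABEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_predictions(results: Iterable, path: str | Path, model_name: str = "ognet") -> None:
    """Write prediction rows (id, group-or-unassigned, confidence, model) as TSV.

    ``results`` are objects with ``sequence_id``, ``group`` and ``confidence``
    attributes; row order follows input order.
    """
    rows = [(r.sequence_id, r.group, f"{r.confidence:.6f}", model_name) for r in results]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str, "model": str})
    if list(df.columns) != PREDICTION_COLUMNS:
        raise ValueError(f"prediction table {path} must have columns {PREDICTION_COLUMNS}")
    return df
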