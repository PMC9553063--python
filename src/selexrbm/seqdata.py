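"""Sequence/count containers and I/O for SELEX round tables.

The universal input record is a *round table*: the set of distinct
fixed-length DNA sequences observed at one selection round, each with the
number of sequencing reads supporting it.  Tables are stored on disk as
header-less two-column CSV/TSV files (``sequence,count``) or as FASTA
(each record counts once; duplicates are collapsed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = "ACGT"
_CHAR_TO_INT = {c: i for i, c in enumerate(ALPHABET)}


class SequenceError(ValueError):
    """Raised for malformed sequences or count tables."""


def encode(sequences) -> np.ndarray:
    """Encode sequences (str or iterable of str) as an (N, L) int8 array.

    A=0, C=1, G=2, T=3.  Raises :class:`SequenceError` on characters
    outside the alphabet or ragged lengths.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    L = len(seqs[0])
    out = np.empty((len(seqs), L), dtype=np.int8)
    for n, s in enumerate(seqs):
        if len(s) != L:
            raise SequenceError(
                f"mixed sequence lengths: expected {L}, got {len(s)} ({s!r})"
            )
        for i, c in enumerate(s):
            code = _CHAR_TO_INT.get(c)
            if code is None:
                raise SequenceError(f"invalid character {c!r} in sequence {s!r}")
            out[n, i] = code
    return out


def decode(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    codes = np.atleast_2d(np.asarray(codes))
    return ["".join(ALPHABET[c] for c in row) for row in codes]


def one_hot(codes: np.ndarray) -> np.ndarray:
    """(N, L) integer codes -> (N, L, 4) one-hot indicator array."""
    codes = np.atleast_2d(np.asarray(codes))
    N, L = codes.shape
    out = np.zeros((N, L, 4), dtype=np.float64)
    out[np.arange(N)[:, None], np.arange(L)[None, :], codes] = 1.0
    return out


def from_one_hot(oh: np.ndarray) -> np.ndarray:
    return np.argmax(oh, axis=-1).astype(np.int8)


@dataclass
class RoundTable:
    """Distinct sequences with read counts at one SELEX round.

    Parameters
    ----------
    sequences : list of str
        Distinct DNA sequences over {A, C, G, T}, all of equal length.
    counts : array of int
        Positive read counts, aligned with ``sequences``.
    round_index : int, optional
        The selection round the table was sequenced at.
    """

    sequences: list[str]
    counts: np.ndarray
    round_index: int | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise SequenceError("sequences and counts have different lengths")
        if len(self.sequences) == 0:
            raise SequenceError("empty round table")
        if np.any(self.counts < 1):
            raise SequenceError("counts must be >= 1")
        if len(set(self.sequences)) != len(self.sequences):
            raise SequenceError("sequences must be unique within a round table")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise SequenceError("all sequences in a table must share one length")
        # encode() validates the alphabet
        self._codes = encode(self.sequences)

    # -- basic properties -------------------------------------------------
    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def n_unique(self) -> int:
        return len(self.sequences)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    @property
    def codes(self) -> np.ndarray:
        """(N, L) integer encoding of the sequences."""
        return self._codes

    def __len__(self):
        return len(self.sequences)

    def __contains__(self, seq: str) -> bool:
        if self._index is None:
            self._index = {s: i for i, s in enumerate(self.sequences)}
        return seq in self._index

    def count_of(self, seq: str) -> int:
        if self._index is None:
            self._index = {s: i for i, s in enumerate(self.sequences)}
        i = self._index.get(seq)
        return 0 if i is None else int(self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sequence": self.sequences, "count": self.counts})

    @classmethod
    def from_records(cls, records, round_index=None) -> "RoundTable":
        """Build from (sequence, count) pairs, accumulating duplicates."""
        acc: dict[str, int] = {}
        for seq, c in records:
            acc[seq] = acc.get(seq, 0) + int(c)
        return cls(list(acc.keys()), np.array(list(acc.values())), round_index)


def read_round_table(
    path, fmt: str | None = None, on_invalid: str = "error", round_index=None
) -> RoundTable:
    """Read a round table from CSV/TSV (``sequence,count``) or FASTA.

    Parameters
    ----------
    fmt : {'csv', 'tsv', 'fasta'}, optional
        Inferred from the file suffix when omitted.
    on_invalid : {'error', 'drop'}
        Sequences with characters outside {A, C, G, T}: ``'error'`` raises
        naming the offending line, ``'drop'`` removes them with a warning.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {
            ".csv": "csv",
            ".tsv": "tsv",
            ".txt": "csv",
            ".fa": "fasta",
            ".fasta": "fasta",
            ".fna": "fasta",
        }.get(suffix)
        if fmt is None:
            raise SequenceError(f"cannot infer format from suffix {suffix!r}")

    records: list[tuple[str, int]] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((str(rec.seq).upper(), 1))
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(sep)
                if len(parts) != 2:
                    raise SequenceError(
                        f"{path}:{lineno}: expected 'sequence{sep}count', got {line!r}"
                    )
                seq = parts[0].strip().upper()
                try:
                    count = int(parts[1])
                except ValueError as exc:
                    raise SequenceError(
                        f"{path}:{lineno}: count is not an integer: {parts[1]!r}"
                    ) from exc
                if count < 1:
                    raise SequenceError(f"{path}:{lineno}: count must be >= 1")
                records.append((seq, count))
    else:
        raise SequenceError(f"unknown format {fmt!r}")

    clean = []
    for lineno, (seq, count) in enumerate(records, start=1):
        if all(c in _CHAR_TO_INT for c in seq):
            clean.append((seq, count))
        elif on_invalid == "drop":
            warnings.warn(f"dropping sequence with invalid characters: {seq!r}")
        else:
            raise SequenceError(
                f"{path}: record {lineno}: invalid characters in {seq!r}"
            )
    if not clean:
        raise SequenceError(f"{path}: no valid records")
    return RoundTable.from_records(clean, round_index=round_index)


def write_round_table(table: RoundTable, path, fmt: str | None = None) -> None:
    """Write a round table as CSV/TSV (``sequence,count``, no header)."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() == ".tsv" else "csv"
    sep = "," if fmt == "csv" else "\t"
    with open(path, "w") as fh:
        for seq, c in zip(table.sequences, table.counts):
            fh.write(f"{seq}{sep}{int(c)}\n")


# -- sequence utilities ---------------------------------------------------

def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(a) != len(b):
        raise SequenceError(
            f"hamming distance needs equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def split_loops(seq: str) -> tuple[str, str]:
    """Split a 40-nt double-loop sequence into (left, right) 20-mers."""
    if len(seq) != 40:
        raise SequenceError(f"split_loops needs a 40-nt sequence, got {len(seq)}")
    return seq[:20], seq[20:]


def distance_to_set(seq: str, table: RoundTable, min_count: int = 1) -> int:
    """Minimum Hamming distance from ``seq`` to table sequences with
    count >= ``min_count``; 0 when the sequence itself qualifies."""
    mask = table.counts >= min_count
    if not mask.any():
        raise SequenceError(f"no table sequences with count >= {min_count}")
    codes = table.codes[mask]
    q = encode(seq)[0]
    if q.shape[0] != table.L:
        raise SequenceError("query length does not match table length")
    return int((codes != q[None, :]).sum(axis=1).min())


def distances_to_set(codes: np.ndarray, table: RoundTable, min_count: int = 1,
                     block: int = 256) -> np.ndarray:
    """Vectorized minimum Hamming distance for many query sequences."""
    mask = table.counts >= min_count
    if not mask.any():
        raise SequenceError(f"no table sequences with count >= {min_count}")
    ref = table.codes[mask]
    codes = np.atleast_2d(codes)
    out = np.empty(len(codes), dtype=np.int64)
    for start in range(0, len(codes), block):
        chunk = codes[start:start + block]
        d = (chunk[:, None, :] != ref[None, :, :]).sum(axis=2)
        out[start:start + block] = d.min(axis=1)
    return out


def collapse_unique(table: RoundTable) -> RoundTable:
    """Forget counts: every distinct sequence gets count 1."""
    return RoundTable(
        list(table.sequences),
        np.ones(table.n_unique, dtype=np.int64),
        round_index=table.round_index,
    )


def train_validation_split(
    table: RoundTable, fraction: float, seed: int
) -> tuple[RoundTable, RoundTable]:
    """Random disjoint split of the *unique* sequences.

    ``fraction`` is the share of unique sequences assigned to the first
    (training) part; counts travel with their sequences.
    """
    if not 0.0 < fraction < 1.0:
        raise SequenceError("fraction must lie strictly between 0 and 1")
    if table.n_unique < 2:
        raise SequenceError("need at least 2 unique sequences to split")
    rng = np.random.default_rng(seed)
    n = table.n_unique
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    idx_train = np.sort(perm[:n_train])
    idx_val = np.sort(perm[n_train:])

    def _sub(idx):
        return RoundTable(
            [table.sequences[i] for i in idx],
            table.counts[idx],
            round_index=table.round_index,
        )

    return _sub(idx_train), _sub(idx_val)
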