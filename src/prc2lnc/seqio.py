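"""Reading, validating, filtering and subsampling nucleotide sequence sets.

Sequences are stored in the DNA alphabet {A, C, G, T, N}; RNA input (U) is
accepted and mapped to T on the way in, since lncRNA sequences arrive both as
transcript (RNA) and genomic (DNA) text.  Class labels distinguish
PRC2-binding ("positive") from PRC2 non-binding ("negative") transcripts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")
POSITIVE = "positive"
NEGATIVE = "negative"
_LABELS = (POSITIVE, NEGATIVE)


class FastaParseError(ValueError):
    """Malformed FASTA input (empty header or empty sequence)."""


class SequenceValidationError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N, U}."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with an optional class label.

    The sequence must already be normalized (uppercase DNA alphabet); use
    :func:`normalize_sequence` or :func:`read_fasta` for raw input.
    """

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise SequenceValidationError(
                f"record {self.id!r}: disallowed character "
                f"{self.sequence[pos]!r} at position {pos}"
            )
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str | None) -> "SequenceRecord":
        return replace(self, label=label)


@dataclass
class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sequence id {dup!r} in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def with_label(self, label: str | None) -> "SequenceSet":
        return SequenceSet([r.with_label(label) for r in self.records], self.name)


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, and validate against the {A,C,G,T,N} alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise SequenceValidationError(
            f"record {record_id!r}: disallowed character {seq[pos]!r} at position {pos}"
        )
    return seq


def read_fasta(path: str | Path, label: str | None = None, name: str | None = None) -> SequenceSet:
    """Read a (multi-)FASTA file into a :class:`SequenceSet`, in file order.

    Sequences are uppercased and U is mapped to T.  An empty file yields an
    empty set.  A record with an empty header or an empty sequence raises
    :class:`FastaParseError`; a character outside {A,C,G,T,N,U} raises
    :class:`SequenceValidationError` naming the position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record #{len(records) + 1} has an empty header")
        raw = str(rec.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, normalize_sequence(raw, rec.id), label))
    return SequenceSet(records, name if name is not None else path.stem)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    """Write a sequence set as wrapped FASTA (ids and order preserved)."""
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV into a mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            seq_id, label = row[0], row[1]
            if label not in _LABELS:
                raise ValueError(f"label for {seq_id!r} must be one of {_LABELS}, got {label!r}")
            out[seq_id] = label
    return out


def write_labels_tsv(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f"{rec.id}\t{rec.label or ''}\n")


def apply_labels(seqs: SequenceSet, labels: dict[str, str]) -> SequenceSet:
    """Attach labels from an id->label mapping; unknown ids stay unlabeled."""
    return SequenceSet(
        [r.with_label(labels.get(r.id, r.label)) for r in seqs], seqs.name
    )


def filter_min_length(seqs: SequenceSet, min_exclusive: int = 100) -> SequenceSet:
    """Keep only records strictly longer than ``min_exclusive`` nucleotides.

    The default retains sequences of more than 100 nt, the length filter used
    to assemble the lncRNA training sets.
    """
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    return SequenceSet([r for r in seqs if r.length > min_exclusive], seqs.name)


def balanced_subsample(seqs: SequenceSet, n: int, seed: int) -> SequenceSet:
    """Sample ``n`` distinct records uniformly without replacement.

    Used to equalize class sizes (e.g. drawing 314 negatives to match 314
    positives).  The original file order of the retained records is preserved,
    and the same seed always yields the same subset.
    """
    if n > len(seqs):
        raise ValueError(f"cannot sample {n} records from a set of {len(seqs)}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(seqs), size=n, replace=False).tolist())
    return SequenceSet([seqs[i] for i in idx], seqs.name)
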