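"""Sequence features: k-word frequencies, PWM hit frequencies, LZ76 complexity.

Three feature families are computed per transcript and assembled into a
samples x features matrix:

* ``kmer:<word>`` — overlapping k-word frequencies on the sense strand,
  normalized by the number of valid (N-free) windows so transcripts of very
  different lengths are comparable;
* ``pwm:<name>`` — the fraction of windows whose position-weight-matrix
  log-probability score reaches a threshold expressed as a fraction of the
  min–max attainable score range, averaged over the two strands;
* ``kc`` — a Lempel–Ziv (1976) phrase-count approximation of Kolmogorov
  complexity, normalized to c * log4(nu) / nu where nu is the N-free length,
  so repetitive (low-complexity) transcripts score low regardless of length.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord, SequenceSet, POSITIVE

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default pseudocount added per column when converting counts to probabilities
DEFAULT_PSEUDOCOUNT = 0.25
#: default PWM hit threshold as a fraction of the min-max score range
DEFAULT_MIN_SCORE_FRACTION = 0.8


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# k-word frequencies
# ---------------------------------------------------------------------------

def all_kmers(k: int) -> list[str]:
    """All 4**k words of length k in lexicographic order."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def _kmer_counts(sequence: str, k: int) -> tuple[dict[str, int], int]:
    """Count overlapping k-words, skipping windows that contain N.

    Returns (counts, number of valid windows).
    """
    counts: dict[str, int] = {}
    valid = 0
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        if "N" in word:
            continue
        valid += 1
        counts[word] = counts.get(word, 0) + 1
    return counts, valid


def kmer_frequencies(seq: SequenceRecord | str, k: int) -> dict[str, float]:
    """Overlapping k-word frequencies on the sense strand.

    Frequencies are counts divided by the number of valid windows and sum to 1
    whenever at least one N-free window exists.  Words not present map to 0
    implicitly (the returned dict holds observed words only).  A sequence with
    no valid window yields an empty (all-zero) spectrum with a logged warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sequence = seq.sequence if isinstance(seq, SequenceRecord) else seq
    counts, valid = _kmer_counts(sequence, k)
    if valid == 0:
        ident = seq.id if isinstance(seq, SequenceRecord) else "<str>"
        logger.warning("sequence %s has no valid %d-mer window; zero spectrum", ident, k)
        return {}
    return {w: c / valid for w, c in counts.items()}


# ---------------------------------------------------------------------------
# Lempel–Ziv 1976 complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityScore:
    """LZ76 phrase count plus its length-normalized form."""

    phrase_count: int
    normalized: float
    length_used: int


def lz76_phrase_count(s: str) -> int:
    """Number of phrases in the LZ76 exhaustive production parse of ``s``.

    Scanning left to right, the current phrase is extended while it occurs as
    a substring of the text seen so far (self-overlap allowed); each phrase is
    the longest such copy plus one fresh symbol.  Repetitive strings parse
    into few phrases: ``AAAAAA`` -> ``A | AAAAA`` -> 2.
    """
    n = len(s)
    if n == 0:
        raise ValueError("cannot parse an empty string")
    c = 0
    i = 0
    while i < n:
        ell = 0
        # extend the copied part while s[i : i+ell+1] occurs in the prefix
        # s[: i+ell] (source may overlap the phrase itself)
        while i + ell < n and s[i : i + ell + 1] in s[: i + ell]:
            ell += 1
        c += 1
        i += ell + 1
    return c


def lz76_complexity(seq: SequenceRecord | str) -> ComplexityScore:
    """LZ76 complexity of a sequence, N bases removed before parsing.

    The normalized score is ``c * log4(nu) / nu`` with ``nu`` the N-free
    length, making the value comparable across the 100–7000 nt length range of
    typical lncRNAs.  For the degenerate single-symbol case (``nu == 1``,
    where the logarithm vanishes) the normalized score is defined as 1.0.
    """
    sequence = seq.sequence if isinstance(seq, SequenceRecord) else seq
    stripped = sequence.replace("N", "")
    if not stripped:
        raise ValueError("sequence is empty after removing N bases")
    c = lz76_phrase_count(stripped)
    nu = len(stripped)
    normalized = 1.0 if nu == 1 else c * math.log(nu, 4) / nu
    return ComplexityScore(phrase_count=c, normalized=normalized, length_used=nu)


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """A position frequency/probability matrix over A, C, G, T.

    ``matrix`` has shape (4, m) with rows in A, C, G, T order.  ``form`` is
    "counts" for raw position frequency matrices (as in JASPAR PFM files) or
    "probabilities" for column-normalized matrices.
    """

    name: str
    matrix: np.ndarray
    form: str = "counts"
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x m with m >= 1")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.name!r}: negative entries")
        if self.form not in ("counts", "probabilities"):
            raise ValueError(f"PWM {self.name!r}: unknown form {self.form!r}")
        if self.form == "probabilities":
            sums = self.matrix.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(f"PWM {self.name!r}: probability columns must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_probabilities(self) -> np.ndarray:
        """Per-column log probabilities after pseudocount regularization."""
        m = self.matrix
        totals = m.sum(axis=0)
        probs = (m + self.pseudocount) / (totals + 4.0 * self.pseudocount)
        return np.log(probs)


def read_jaspar_pfms(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PFM text: '>name' then four A/C/G/T rows of counts.

    Both plain rows of numbers and the bracketed ``A  [ 4 19 0 ... ]`` style
    are accepted.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"PWM {name!r}: expected 4 rows (A, C, G, T), got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"PWM {name!r}: ragged rows")
        pwms.append(PWM(name, np.array(rows)))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError("PFM header without a name")
                continue
            body = line
            if body[0] in "ACGTacgt" and (len(body) == 1 or not body[1].isdigit()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(tok) for tok in body.split()])
    flush()
    return pwms


def write_jaspar_pfms(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for base, row in zip(_BASES, pwm.matrix):
                fh.write(base + "  [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


def _encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N -> 4."""
    out = np.full(len(sequence), 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def _strand_hit_fraction(codes: np.ndarray, logp: np.ndarray, threshold: float) -> float:
    """Fraction of valid (N-free) windows scoring >= threshold on one strand."""
    m = logp.shape[1]
    n_windows = codes.size - m + 1
    if n_windows < 1:
        return 0.0
    # pad an extra log-prob row for N so indexing is safe; N windows are
    # masked out afterwards
    padded = np.vstack([logp, np.zeros((1, m))])
    scores = np.zeros(n_windows)
    invalid = np.zeros(n_windows, dtype=bool)
    for j in range(m):
        col = codes[j : j + n_windows]
        scores += padded[col, j]
        invalid |= col == 4
    valid = ~invalid
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0
    hits = int(np.sum(scores[valid] >= threshold - 1e-9))
    return hits / n_valid


def pwm_hit_frequency(
    seq: SequenceRecord | str,
    pwm: PWM,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
) -> float:
    """Strand-averaged fraction of windows matching a PWM.

    The PWM is converted to per-column log probabilities (with pseudocount);
    a window is a hit when its summed log-probability reaches
    ``min + min_score_fraction * (max - min)`` of the attainable score range.
    The forward frequency and the frequency on the reverse complement are
    averaged, so the feature is strand-symmetric.  A motif wider than the
    sequence yields 0 with a logged warning.
    """
    if not 0.0 <= min_score_fraction <= 1.0:
        raise ValueError("min_score_fraction must be in [0, 1]")
    sequence = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if pwm.width > len(sequence):
        ident = seq.id if isinstance(seq, SequenceRecord) else "<str>"
        logger.warning(
            "motif %s (width %d) longer than sequence %s (%d nt); frequency 0",
            pwm.name, pwm.width, ident, len(sequence),
        )
        return 0.0
    logp = pwm.log_probabilities()
    lo = logp.min(axis=0).sum()
    hi = logp.max(axis=0).sum()
    threshold = lo + min_score_fraction * (hi - lo)
    fwd = _strand_hit_fraction(_encode(sequence), logp, threshold)
    rev = _strand_hit_fraction(_encode(reverse_complement(sequence)), logp, threshold)
    return 0.5 * (fwd + rev)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

#: signature for user-supplied extra feature extractors: record -> {name: value}
FeatureExtension = Callable[[SequenceRecord], dict[str, float]]


@dataclass
class FeatureMatrix:
    """Samples x named features, optionally with 0/1 labels (1 = PRC2-binding).

    ``data`` is a DataFrame indexed by sample id with namespaced feature
    columns (``kmer:*``, ``pwm:*``, ``kc``); ``labels`` is an int array
    aligned with the rows, or None for unlabeled query matrices.
    """

    data: pd.DataFrame
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.data),):
                raise ValueError("labels length must match the number of rows")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        return FeatureMatrix(self.data[list(names)].copy(), self.labels)

    def subset_samples(self, index: np.ndarray) -> "FeatureMatrix":
        labels = None if self.labels is None else self.labels[index]
        return FeatureMatrix(self.data.iloc[index].copy(), labels)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.labels is not None:
            out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(df, labels)


def build_feature_matrix(
    seqs: SequenceSet,
    k: int = 6,
    pwms: Sequence[PWM] = (),
    include_kc: bool = True,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
    extensions: Sequence[FeatureExtension] = (),
) -> FeatureMatrix:
    """Assemble the feature matrix for a sequence set.

    Columns are all 4**k k-words (``kmer:*``), one ``pwm:<name>`` column per
    matrix, the ``kc`` normalized complexity when requested, plus any columns
    produced by user extension functions.  Rows follow the set order.  Labels
    are attached when every record carries one (positive -> 1).
    """
    if len(seqs) == 0:
        raise ValueError("cannot build a feature matrix from an empty set")
    words = all_kmers(k)
    word_index = {w: j for j, w in enumerate(words)}
    kmer_block = np.zeros((len(seqs), len(words)))
    for i, rec in enumerate(seqs):
        for w, f in kmer_frequencies(rec, k).items():
            kmer_block[i, word_index[w]] = f

    columns: dict[str, np.ndarray] = {f"kmer:{w}": kmer_block[:, j] for j, w in enumerate(words)}
    for pwm in pwms:
        columns[f"pwm:{pwm.name}"] = np.array(
            [pwm_hit_frequency(rec, pwm, min_score_fraction) for rec in seqs]
        )
    if include_kc:
        columns["kc"] = np.array([lz76_complexity(rec).normalized for rec in seqs])
    for ext in extensions:
        ext_rows = [ext(rec) for rec in seqs]
        for key in ext_rows[0]:
            columns[key] = np.array([row[key] for row in ext_rows])

    data = pd.DataFrame(columns, index=pd.Index(seqs.ids, name="sample_id"))
    labels = None
    if all(r.label is not None for r in seqs):
        labels = np.array([1 if r.label == POSITIVE else 0 for r in seqs])
    return FeatureMatrix(data, labels)
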