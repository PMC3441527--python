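"""Class-difference feature selection and degenerate consensus motifs.

Each feature column is compared between the PRC2-binding (positive) and
non-binding (negative) classes with a two-sample t-test (Welch by default);
features with p below a chosen significance level (0.05 liberal / 0.01
conservative) are selected, without multiple-testing correction.  The
enriched k-words of each class are summarized as IUPAC degenerate consensus
strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class ConsensusMotif:
    """A positionwise IUPAC consensus over a set of equal-length k-words."""

    iupac: str
    support: int
    k: int


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample t-test with unequal variances (Welch).

    Degenerate inputs are resolved deterministically: two constant equal
    samples give (0, 1); two constant different samples give (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return float(np.inf if x[0] > y[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def select_features(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sample t-tests between the classes.

    Returns the full audit table (one row per feature) with columns
    ``t``, ``p``, ``mean_positive``, ``mean_negative``, ``enriched_class``,
    ``degenerate`` and ``selected`` (p < alpha; on the Benjamini–Hochberg
    adjusted p when ``bh_correction``).  Raw, uncorrected thresholds are the
    default, matching the liberal/conservative 0.05 / 0.01 protocol.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if matrix.labels is None:
        raise ValueError("selection requires a labeled matrix")
    labels = matrix.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    X = matrix.values
    pos = X[labels == 1]
    neg = X[labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trip scipy's precision-loss warning; they are
        # resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    var_pos = pos.var(axis=0, ddof=1)
    var_neg = neg.var(axis=0, ddof=1)
    degenerate = (var_pos == 0) & (var_neg == 0)
    equal_const = degenerate & (mean_pos == mean_neg)
    diff_const = degenerate & ~equal_const
    t[equal_const] = 0.0
    p[equal_const] = 1.0
    t[diff_const] = np.where(mean_pos[diff_const] > mean_neg[diff_const], np.inf, -np.inf)
    p[diff_const] = 0.0

    p_effective = p
    if bh_correction:
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        ranked = p[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        p_effective = np.minimum(adj, 1.0)

    enriched = np.where(
        mean_pos > mean_neg, "positive", np.where(mean_pos < mean_neg, "negative", "")
    )
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_positive": mean_pos,
            "mean_negative": mean_neg,
            "enriched_class": enriched,
            "degenerate": degenerate,
            "selected": p_effective < alpha,
        },
        index=pd.Index(matrix.feature_names, name="feature"),
    )
    return table


def selected_features(table: pd.DataFrame) -> list[str]:
    """Names of the features flagged as selected in an audit table."""
    return list(table.index[table["selected"]])


def selected_counts_by_namespace(table: pd.DataFrame) -> dict[str, int]:
    """Selected-feature counts per namespace (kmer / pwm / kc / other)."""
    out = {"kmer": 0, "pwm": 0, "kc": 0, "other": 0}
    for name in table.index[table["selected"]]:
        if name.startswith("kmer:"):
            out["kmer"] += 1
        elif name.startswith("pwm:"):
            out["pwm"] += 1
        elif name == "kc":
            out["kc"] += 1
        else:
            out["other"] += 1
    return out


def consensus_iupac(words: Sequence[str], min_freq: float = 0.1) -> ConsensusMotif:
    """Positionwise IUPAC consensus of equal-length k-words.

    At each position the consensus code covers every nucleotide whose relative
    frequency among the words is at least ``min_freq``; e.g. {AAAA, TTTT} ->
    WWWW.  This is a deliberately simple summarization of an enriched word
    set, not a motif alignment.
    """
    if not words:
        raise ValueError("need at least one word")
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all words must have the same length")
    if any(set(w) - set("ACGT") for w in words):
        raise ValueError("words must be over {A, C, G, T}")
    n = len(words)
    letters = []
    for pos in range(k):
        freqs: dict[str, int] = {}
        for w in words:
            freqs[w[pos]] = freqs.get(w[pos], 0) + 1
        kept = frozenset(b for b, c in freqs.items() if c / n >= min_freq)
        if not kept:  # every base below min_freq; fall back to all observed
            kept = frozenset(freqs)
        letters.append(IUPAC_CODES[kept])
    return ConsensusMotif("".join(letters), support=n, k=k)


def enriched_kmer_consensus(
    table: pd.DataFrame, enriched_class: str, min_freq: float = 0.1
) -> ConsensusMotif | None:
    """Consensus of the selected k-words enriched in one class, or None."""
    rows = table[(table["selected"]) & (table["enriched_class"] == enriched_class)]
    words = [name.split(":", 1)[1] for name in rows.index if name.startswith("kmer:")]
    if not words:
        return None
    return consensus_iupac(words, min_freq=min_freq)
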