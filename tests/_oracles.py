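"""Independent definition-level reference implementations used as oracles.

These deliberately avoid the code paths (and even the string primitives)
used by the package: the LZ76 reference matches characters pointer-by-
pointer instead of using substring search, and the alignment references
enumerate every possible alignment explicitly instead of running dynamic
programming.
"""

from __future__ import annotations

from functools import lru_cache

NEG_INF = float("-inf")


def lz76_reference(s: str) -> int:
    """LZ76 exhaustive-production phrase count, straight from the definition.

    At position i, the longest reproducible extension is the largest l such
    that some start q < i satisfies s[q + t] == s[i + t] for all t < l
    (self-overlapping copies allowed); the phrase is that copy plus one fresh
    symbol (truncated at the end of the string).
    """
    n = len(s)
    if n == 0:
        raise ValueError("empty string")
    c = 0
    i = 0
    while i < n:
        best = 0
        for q in range(i):
            t = 0
            while i + t < n and s[q + t] == s[i + t]:
                t += 1
            best = max(best, t)
        # phrase covers the copied part plus one new symbol
        step = min(best + 1, n - i)
        c += 1
        i += step
    return c


def _pair_score(x: str, y: str, match: int, mismatch: int) -> int:
    return match if (x == y and x != "N") else mismatch


def brute_force_global(
    a: str, b: str, match: int = 1, mismatch: int = -3,
    gap_open: int = -10, gap_extend: int = -10,
) -> float:
    """Optimal global alignment score by exhaustive enumeration of every
    alignment path (gap of length L costs gap_open + (L-1) * gap_extend).
    No dynamic programming: the recursion walks all move sequences."""
    la, lb = len(a), len(b)
    best = [NEG_INF]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            walk(i + 1, j + 1, score + _pair_score(a[i], b[j], match, mismatch), "M")
        if i < la:
            walk(i + 1, j, score + (gap_extend if last == "A" else gap_open), "A")
        if j < lb:
            walk(i, j + 1, score + (gap_extend if last == "B" else gap_open), "B")

    walk(0, 0, 0.0, "-")
    return best[0]


def brute_force_local(
    a: str, b: str, match: int = 1, mismatch: int = -3,
    gap_open: int = -10, gap_extend: int = -10,
) -> float:
    """Optimal local alignment score: the best global score over every pair
    of substrings, floored at 0 (the empty alignment)."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            sub_a = a[i0:i1]
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(
                        best,
                        _cached_global(sub_a, b[j0:j1], match, mismatch, gap_open, gap_extend),
                    )
    return best


@lru_cache(maxsize=None)
def _cached_global(a, b, match, mismatch, gap_open, gap_extend):
    return brute_force_global(a, b, match, mismatch, gap_open, gap_extend)
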