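"""Independent oracles shared across tests.

These deliberately avoid the implementation's code paths: the alignment
oracle is a memoized top-down recursion over (i, j, previous-op) rather than
the three-matrix forward DP, and `enumerate_alignment_scores` enumerates
every complete alignment path explicitly (used on tiny inputs to validate
the recursive oracle itself).
"""

from __future__ import annotations

import itertools
import math
import re
from functools import lru_cache


def affine_oracle_score(
    query: str,
    reference: str,
    match: int = 2,
    mismatch: int = 1,
    gap_open: int = 8,
    gap_extend: int = 4,
) -> int:
    """Best global alignment score by memoized recursion over the last op."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(query) and j == len(reference):
            return 0
        cands = []
        if i < len(query) and j < len(reference):
            s = match if query[i] == reference[j] else -mismatch
            cands.append(s + best(i + 1, j + 1, "M"))
        if j < len(reference):  # deletion: consume reference
            cost = gap_extend if last == "D" else gap_open
            cands.append(-cost + best(i, j + 1, "D"))
        if i < len(query):  # insertion: consume query
            cost = gap_extend if last == "I" else gap_open
            cands.append(-cost + best(i + 1, j, "I"))
        return max(cands)

    return int(best(0, 0, ""))


def enumerate_alignment_scores(
    query: str,
    reference: str,
    match: int = 2,
    mismatch: int = 1,
    gap_open: int = 8,
    gap_extend: int = 4,
) -> int:
    """Max score over an explicit enumeration of every global alignment path."""

    best = -math.inf

    def walk(i: int, j: int, last: str, score: int) -> None:
        nonlocal best
        if i == len(query) and j == len(reference):
            best = max(best, score)
            return
        if i < len(query) and j < len(reference):
            s = match if query[i] == reference[j] else -mismatch
            walk(i + 1, j + 1, "M", score + s)
        if j < len(reference):
            walk(i, j + 1, "D", score - (gap_extend if last == "D" else gap_open))
        if i < len(query):
            walk(i + 1, j, "I", score - (gap_extend if last == "I" else gap_open))

    walk(0, 0, "", 0)
    return int(best)


def regex_homopolymers(sequence: str, min_length: int = 5) -> list[tuple[int, int, str]]:
    """(start, end, base) of maximal runs >= min_length, by regex backreference."""
    return [
        (m.start(), m.end(), m.group(1))
        for m in re.finditer(r"([ACGT])\1*", sequence)
        if m.end() - m.start() >= min_length
    ]


def jsd_direct(p, q) -> float:
    """JSD(p, q) = H(m) - (H(p) + H(q))/2 with base-2 entropies."""

    def entropy(d) -> float:
        return -sum(x * math.log2(x) for x in d if x > 0)

    m = [(a + b) / 2 for a, b in itertools.zip_longest(p, q, fillvalue=0.0)]
    pp = list(p) + [0.0] * (len(m) - len(p))
    qq = list(q) + [0.0] * (len(m) - len(q))
    return entropy(m) - (entropy(pp) + entropy(qq)) / 2
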