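"""Intramolecular secondary structure of the 19-nt guide strand.

Maximum base-pair folding (Nussinov dynamic programming) over Watson–Crick
pairs plus the G·U wobble, with a minimum hairpin loop of 3 unpaired bases.
Maximum matching rather than minimum free energy is deliberate: it needs no
external folding engine, is exactly checkable against brute-force
enumeration at small lengths, and for 19-mers the "does the guide fold back
on itself" signal is what the downstream features consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

MIN_HAIRPIN_LOOP = 3

_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


@dataclass(frozen=True)
class StructureContent:
    """Summary of the maximum-pairing fold of one strand.

    paired_fraction
        2·(max pairs)/len(seq), in [0, 1].
    max_stem
        Longest run of stacked pairs (i,j),(i+1,j−1),… in the canonical
        traceback structure.
    hairpin_flag
        1 if the traced structure contains a stem of ≥ 2 stacked pairs
        closing a loop — i.e. a *bona fide* hairpin rather than one
        isolated pair.
    """

    paired_fraction: float
    max_stem: int
    hairpin_flag: int


def max_pairs(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> int:
    """Maximum number of nested base pairs (Nussinov recursion)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def dp(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = dp(i, j - 1)
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = dp(i, k - 1) if k > i else 0
                best = max(best, 1 + left + dp(k + 1, j - 1))
        return best

    result = dp(0, n - 1)
    dp.cache_clear()
    return result


def _traceback(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> list[tuple[int, int]]:
    """One canonical maximum-pairing structure as a sorted pair list.

    Ties in the DP are broken deterministically (leftmost pairing partner
    first), so identical sequences always yield identical structures.
    """
    n = len(seq)
    table: dict[tuple[int, int], int] = {}

    def dp(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        if (i, j) in table:
            return table[i, j]
        best = dp(i, j - 1)
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = dp(i, k - 1) if k > i else 0
                best = max(best, 1 + left + dp(k + 1, j - 1))
        table[i, j] = best
        return best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        if j - i <= min_loop:
            return
        if dp(i, j) == dp(i, j - 1):
            trace(i, j - 1)
            return
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = dp(i, k - 1) if k > i else 0
                if dp(i, j) == 1 + left + dp(k + 1, j - 1):
                    pairs.append((k, j))
                    if k > i:
                        trace(i, k - 1)
                    trace(k + 1, j - 1)
                    return
        raise AssertionError("traceback failed")  # pragma: no cover

    trace(0, n - 1)
    return sorted(pairs)


def structure_content(seq: str) -> StructureContent:
    """Fold ``seq`` by maximum matching and summarise the structure."""
    pairs = _traceback(seq)
    n = len(seq)
    if not pairs:
        return StructureContent(0.0, 0, 0)
    pair_set = set(pairs)
    max_stem = 0
    for (i, j) in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its stem
        stem = 1
        while (i + stem, j - stem) in pair_set:
            stem += 1
        max_stem = max(max_stem, stem)
    return StructureContent(
        paired_fraction=2.0 * len(pairs) / n,
        max_stem=max_stem,
        hairpin_flag=int(max_stem >= 2),
    )
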