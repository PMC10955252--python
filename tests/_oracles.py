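"""Independent brute-force oracles used by the test suite.

Occurrence counts come from a naively sorted suffix list of the doubled
text plus binary search — no BWT machinery — and SMEM enumeration is by
direct maximality checks on substring counts.
"""
from __future__ import annotations

from bisect import bisect_left

from sstseed.fmindex import revcomp


class SubstringCounter:
    """Occurrence counts over seq + revcomp(seq) by naive suffix sorting."""

    def __init__(self, seq: str):
        self.text = seq + "#" + revcomp(seq)  # separator blocks junction matches
        self.suffixes = sorted(self.text[i:] for i in range(len(self.text)))

    def count(self, pattern: str) -> int:
        if "#" in pattern or not pattern:
            return 0
        lo = bisect_left(self.suffixes, pattern)
        hi = bisect_left(self.suffixes, pattern + "\x7f")
        return hi - lo


def maximal_matches(counter: SubstringCounter, read: str, min_intv: int,
                    pivot: int | None = None) -> set[tuple[int, int]]:
    """All (qbeg, qend) of maximal exact matches with count >= min_intv.

    A match is maximal when neither single-base extension (within read
    bounds) keeps the occurrence count at or above min_intv; with counts
    monotone under extension this equals non-containment in any longer
    qualifying match.  With `pivot` set, only matches covering that position
    are returned (the SuperMEM1 contract).
    """
    L = len(read)
    out: set[tuple[int, int]] = set()
    starts = range(L) if pivot is None else range(pivot + 1)
    for i in starts:
        j_lo = i + 1 if pivot is None else pivot + 1
        # longest j with count(read[i:j]) >= min_intv, if any
        if counter.count(read[i:j_lo]) < min_intv:
            continue
        j = j_lo
        while j < L and counter.count(read[i:j + 1]) >= min_intv:
            j += 1
        left_ok = i == 0 or counter.count(read[i - 1:j]) < min_intv
        if left_ok:
            out.add((i, j))
    return out


def naive_sal_positions(seq: str) -> list[int]:
    """Expected sal(r) for every rank, by naive suffix sorting.

    Mirrors the documented index layout for a single N-free record: the text
    is seq, a sentinel, revcomp(seq), a sentinel; sentinels sort below the
    bases and among themselves by text order.
    """
    keys = {"A": 2, "C": 3, "G": 4, "T": 5}
    text = [keys[c] for c in seq] + [0] + [keys[c] for c in revcomp(seq)] + [1]
    order = sorted(range(len(text)), key=lambda i: text[i:])
    return [i for i in order]


def smem_set(counter: SubstringCounter, read: str, min_intv: int = 1,
             min_len: int = 1, pivot: int | None = None
             ) -> set[tuple[int, int]]:
    return {(i, j) for i, j in maximal_matches(counter, read, min_intv, pivot)
            if j - i >= min_len}
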