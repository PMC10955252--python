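"""SMEM collection in the BWA-MEM style.

``super_mem1`` returns all super-maximal exact matches covering one pivot
position: a forward pass extends right from the pivot base, retaining an
exact match whenever the interval size changes (a shorter match with the
same size as a longer one can never be super-maximal), then a backward pass
extends every retained match left to its limit and keeps the matches not
contained in longer ones.

``collect_smems`` sweeps the whole read with min-intv = 1, re-pivoting one
past the right end of the longest SMEM of each round.  ``reseed`` runs a
second pass at the middle base of every sufficiently long SMEM with the
interval-size threshold raised above the SMEM's own occurrence count, to
recover seeds hidden inside long repeats.  ``materialize_seeds`` resolves
each retained match to genome positions, one suffix-array lookup per rank.

Every index access is routed through an accessor object so that a cache can
interpose; :class:`DirectAccessor` is the cache-free baseline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Protocol, Sequence

import numpy as np

from .fmindex import BiInterval, FmdIndex


@dataclass(frozen=True)
class SeedingParams:
    """Knobs of the two-stage SMEM search (BWA-MEM defaults)."""

    min_intv: int = 1          # interval-size floor of the first pass
    min_seed_len: int = 19     # matches shorter than this never become seeds
    reseed_factor: float = 1.5  # -r: reseed SMEMs longer than min_seed_len * r
    max_occ: int = 500         # skip SAL for matches with more occurrences
    batch_size: int = 512      # reads sharing one cache before reset

    def __post_init__(self) -> None:
        if self.min_intv < 1 or self.min_seed_len < 1 or self.batch_size < 1:
            raise ValueError("min_intv, min_seed_len, batch_size must be >= 1")
        if self.reseed_factor <= 1.0:
            raise ValueError("reseed_factor must be > 1")


class ExactMatch(NamedTuple):
    """A read substring [qbeg, qend) with its bi-interval."""

    qbeg: int
    qend: int
    ival: BiInterval

    @property
    def length(self) -> int:
        return self.qend - self.qbeg


#: An ExactMatch that passed the maximality filter of super_mem1.
Smem = ExactMatch


class Seed(NamedTuple):
    """One genomic occurrence of an exact match."""

    qbeg: int
    qend: int
    rbeg: int
    strand: str
    interval_size: int
    origin: str  # "smem" | "reseed"

    @property
    def length(self) -> int:
        return self.qend - self.qbeg


class IndexAccessor(Protocol):
    """Extension/lookup provider; the trie cache implements the same surface."""

    def start_read(self) -> None: ...
    def fwd_init(self, b: int) -> tuple[object, BiInterval]: ...
    def fwd_extend(self, h: object, b: int) -> tuple[object, BiInterval]: ...
    def bwd_init(self, read: np.ndarray, qbeg: int, qend: int,
                 ival: BiInterval) -> object: ...
    def bwd_extend(self, h: object, b: int) -> tuple[object, BiInterval]: ...
    def sal(self, rank: int) -> int: ...


class DirectAccessor:
    """Uncached accessor: every request goes straight to the FM-index."""

    def __init__(self, index: FmdIndex, counters=None):
        from .sstcache import OpCounters
        self.index = index
        self.counters = counters if counters is not None else OpCounters()

    def start_read(self) -> None:
        pass

    def fwd_init(self, b: int):
        ival = self.index.base_interval(b)
        return ival, ival

    def fwd_extend(self, h: BiInterval, b: int):
        self.counters.bwt_queries += 1
        self.counters.bwt_real += 1
        ival = self.index.extend_forward(h, b)
        return ival, ival

    def bwd_init(self, read, qbeg, qend, ival: BiInterval):
        return ival

    def bwd_extend(self, h: BiInterval, b: int):
        self.counters.bwt_queries += 1
        self.counters.bwt_real += 1
        ival = self.index.extend_backward(h, b)
        return ival, ival

    def sal(self, rank: int) -> int:
        self.counters.sal_queries += 1
        self.counters.sal_real += 1
        return self.index.sal(rank)


def super_mem1(read: np.ndarray, pivot: int, min_intv: int,
               acc: IndexAccessor) -> list[Smem]:
    """All SMEMs covering `pivot` with interval size >= min_intv.

    `read` is a uint8 code array; codes > 3 (N) terminate extension on
    either side.  Returned matches are sorted by qbeg ascending.
    """
    L = len(read)
    if not 0 <= pivot < L:
        raise ValueError(f"pivot {pivot} outside read of length {L}")
    b = int(read[pivot])
    if b > 3:
        return []
    h, ik = acc.fwd_init(b)
    if ik.s < min_intv:
        return []

    # forward pass: retain a match each time the interval size changes
    fwd: list[tuple[int, BiInterval]] = []  # (qend, ival)
    ik_end = pivot + 1
    i = pivot + 1
    while i < L and read[i] <= 3:
        h, ok = acc.fwd_extend(h, int(read[i]))
        if ok.s != ik.s:
            fwd.append((ik_end, ik))
            if ok.s < min_intv:
                break
        ik = ok
        ik_end = i + 1
        i += 1
    else:
        fwd.append((ik_end, ik))

    # backward pass over the retained matches, longest first
    prev: list[tuple[int, BiInterval, object]] = []
    for qend, ival in reversed(fwd):
        bh = acc.bwd_init(read, pivot, qend, ival)
        prev.append((qend, ival, bh))

    mems: list[Smem] = []
    i = pivot - 1
    while True:
        c = int(read[i]) if i >= 0 else -1
        if c > 3:
            c = -1
        curr: list[tuple[int, BiInterval, object]] = []
        for qend, ival, bh in prev:
            if c >= 0:
                nh, ok = acc.bwd_extend(bh, c)
            if c < 0 or ok.s < min_intv:
                if not curr:  # a longer retained match is still alive -> contained
                    if not mems or i + 1 < mems[-1].qbeg:
                        mems.append(Smem(i + 1, qend, ival))
            elif not curr or ok.s != curr[-1][1].s:
                curr.append((qend, ok, nh))
        if not curr:
            break
        prev = curr
        i -= 1

    mems.reverse()
    return mems


def collect_smems(read: np.ndarray, params: SeedingParams,
                  acc: IndexAccessor) -> list[Smem]:
    """First seeding pass: all SMEMs across the read at min_intv, deduplicated
    and filtered to length >= min_seed_len."""
    L = len(read)
    out: list[Smem] = []
    pivot = 0
    while pivot < L:
        if read[pivot] > 3:
            pivot += 1
            continue
        mems = super_mem1(read, pivot, params.min_intv, acc)
        if not mems:
            pivot += 1
            continue
        longest = max(mems, key=lambda m: m.qend - m.qbeg)
        pivot = longest.qend
        out.extend(mems)
    seen: set[tuple[int, int]] = set()
    smems: list[Smem] = []
    for m in out:
        key = (m.qbeg, m.qend)
        if key not in seen and m.length >= params.min_seed_len:
            seen.add(key)
            smems.append(m)
    return smems


def reseed(smem: Smem, read: np.ndarray, params: SeedingParams,
           acc: IndexAccessor) -> list[Smem]:
    """Second pass at the middle base of a long SMEM with a raised threshold.

    Triggered when the SMEM is at least min_seed_len * reseed_factor long;
    the new threshold is the SMEM's occurrence count + 1 so only matches
    strictly more repetitive than the trigger are returned.
    """
    if smem.length < params.min_seed_len * params.reseed_factor:
        return []
    mid = (smem.qbeg + smem.qend) // 2
    mems = super_mem1(read, mid, smem.ival.s + 1, acc)
    return [m for m in mems if m.length >= params.min_seed_len]


def materialize_seeds(matches: Sequence[tuple[Smem, str]],
                      params: SeedingParams, acc: IndexAccessor,
                      index: FmdIndex) -> list[Seed]:
    """Resolve matches to genome positions: one SAL per rank, capped at max_occ.

    Matches with more than max_occ occurrences are skipped entirely.  Output
    is sorted by (qbeg, rbeg) with full-tuple tie-breaks for determinism.
    """
    seeds: list[Seed] = []
    for m, origin in matches:
        if m.ival.s > params.max_occ:
            continue
        for rank in range(m.ival.k, m.ival.k + m.ival.s):
            p = acc.sal(rank)
            rbeg, strand = index.position(p, m.length)
            seeds.append(Seed(m.qbeg, m.qend, rbeg, strand, m.ival.s, origin))
    seeds.sort(key=lambda s: (s.qbeg, s.rbeg, s.qend, s.strand, s.origin))
    return seeds


def seed_read(read: np.ndarray, params: SeedingParams, acc: IndexAccessor,
              index: FmdIndex) -> list[Seed]:
    """Full per-read pipeline on an N-free code array: collect, reseed, locate."""
    smems = collect_smems(read, params, acc)
    pool: list[tuple[Smem, str]] = [(m, "smem") for m in smems]
    seen = {(m.qbeg, m.qend) for m in smems}
    for m in smems:
        for rm in reseed(m, read, params, acc):
            key = (rm.qbeg, rm.qend)
            if key not in seen:
                seen.add(key)
                pool.append((rm, "reseed"))
    return materialize_seeds(pool, params, acc, index)


def seed_sequence(seq: str, params: SeedingParams, acc: IndexAccessor,
                  index: FmdIndex) -> list[Seed]:
    """Seed a read given as a string; segments at N and restores offsets."""
    from .fmindex import encode
    codes = encode(seq)
    L = codes.size
    seeds: list[Seed] = []
    i = 0
    while i < L:
        if codes[i] == 4:
            i += 1
            continue
        j = i
        while j < L and codes[j] != 4:
            j += 1
        for s in seed_read(codes[i:j], params, acc, index):
            seeds.append(Seed(s.qbeg + i, s.qend + i, s.rbeg, s.strand,
                              s.interval_size, s.origin))
        i = j
    seeds.sort(key=lambda s: (s.qbeg, s.rbeg, s.qend, s.strand, s.origin))
    return seeds
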