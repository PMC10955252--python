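"""SMEM search tries: a per-batch cache for BWT-extend and SAL results.

Two tries mirror the two stages of SuperMEM1.  The *forward* trie stores, at
each node, the bi-interval of the string spelled from the root to that node;
a downward edge is one forward BWT-extend, so every prefix that any read in
the batch has ever extended is answered from the trie on the next request.
The *backward* trie indexes strings from their last character (an edge
prepends a base), so the exact matches handed over by the forward stage are
inserted character by character in reverse order.  Insertion can create
interior nodes whose interval is not yet known (marked with size -1); they
are filled lazily, top-down from the nearest known ancestor, only if a
backward extension is later requested there.

Suffix-array lookups are memoized per batch keyed by rank, which subsumes
merging of identical and overlapping intervals: the number of real lookups
in a batch is exactly the size of the union of all requested rank ranges.

Caching is transparent: every answer equals what the uncached index returns,
so the seed output is byte-identical with the cache on or off; only the
operation counters differ.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fmindex import BiInterval, FmdIndex

UNKNOWN = -1  # interval-size marker of a lazily created backward-trie node


@dataclass
class OpCounters:
    """Tallies of issued queries vs. queries that actually touched the index."""

    bwt_queries: int = 0
    bwt_real: int = 0
    sal_queries: int = 0
    sal_real: int = 0

    def merged(self, other: "OpCounters") -> "OpCounters":
        return OpCounters(self.bwt_queries + other.bwt_queries,
                          self.bwt_real + other.bwt_real,
                          self.sal_queries + other.sal_queries,
                          self.sal_real + other.sal_real)

    @property
    def real_ops(self) -> int:
        return self.bwt_real + self.sal_real

    @property
    def queries(self) -> int:
        return self.bwt_queries + self.sal_queries

    def to_dict(self) -> dict:
        return {
            "bwt_queries": self.bwt_queries,
            "bwt_real": self.bwt_real,
            "sal_queries": self.sal_queries,
            "sal_real": self.sal_real,
        }


class _Trie:
    """Node pool with integer handles; 4 child slots per node.

    Interval components are kept in parallel lists; ``s == UNKNOWN`` marks an
    empty node.  Parent links are only walked by the backward trie's lazy
    fill.
    """

    __slots__ = ("child", "k", "l", "s", "parent", "pbase")

    def __init__(self, root_ival: BiInterval):
        self.child = [-1, -1, -1, -1]
        self.k = [root_ival.k]
        self.l = [root_ival.l]
        self.s = [root_ival.s]
        self.parent = [-1]
        self.pbase = [-1]

    def __len__(self) -> int:
        return len(self.s)

    def new_node(self, parent: int, base: int, ival: Optional[BiInterval]) -> int:
        h = len(self.s)
        self.child.extend((-1, -1, -1, -1))
        if ival is None:
            self.k.append(0)
            self.l.append(0)
            self.s.append(UNKNOWN)
        else:
            self.k.append(ival.k)
            self.l.append(ival.l)
            self.s.append(ival.s)
        self.parent.append(parent)
        self.pbase.append(base)
        self.child[parent * 4 + base] = h
        return h

    def ival(self, h: int) -> BiInterval:
        return BiInterval(self.k[h], self.l[h], self.s[h])

    def set_ival(self, h: int, ival: BiInterval) -> None:
        self.k[h] = ival.k
        self.l[h] = ival.l
        self.s[h] = ival.s

    def known(self, h: int) -> bool:
        return self.s[h] != UNKNOWN


class SstAccessor:
    """Index accessor backed by forward/backward tries and a SAL memo.

    Implements the same protocol as :class:`~sstseed.seeding.DirectAccessor`;
    ``batch_size`` reads share the cache before it is reset to the root and
    its four precomputed single-base children (single-base intervals come
    from the index's cumulative counts, costing no FM-index access in either
    the cached or the uncached path).
    """

    def __init__(self, index: FmdIndex, counters: Optional[OpCounters] = None,
                 batch_size: int = 512, sal_merge: bool = True):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.index = index
        self.counters = counters if counters is not None else OpCounters()
        self.batch_size = batch_size
        self.sal_merge = sal_merge
        self.batches_started = 0
        self._reads_in_batch = 0
        self._init_batch()

    # -- batch lifecycle -----------------------------------------------------

    def _init_batch(self) -> None:
        root = self.index.empty_interval()
        self.fwd = _Trie(root)
        self.bwd = _Trie(root)
        for b in range(4):
            ival = self.index.base_interval(b)
            self.fwd.new_node(0, b, ival)
            self.bwd.new_node(0, b, ival)
        self._sal_memo: dict[int, int] = {}

    def batch_reset(self) -> None:
        """Drop both tries and the SAL memo; cumulative counters persist."""
        self._init_batch()
        self._reads_in_batch = 0

    def start_read(self) -> None:
        if self._reads_in_batch >= self.batch_size:
            self.batch_reset()
        if self._reads_in_batch == 0:
            self.batches_started += 1
        self._reads_in_batch += 1

    # -- forward trie --------------------------------------------------------

    def fwd_init(self, b: int) -> tuple[int, BiInterval]:
        h = self.fwd.child[b]  # root children precomputed at batch start
        return h, self.fwd.ival(h)

    def forward_query(self, h: int, b: int) -> tuple[int, BiInterval]:
        """Child of forward-trie node h along base b (the interval of Pb)."""
        self.counters.bwt_queries += 1
        t = self.fwd
        ch = t.child[h * 4 + b]
        if ch >= 0:
            return ch, t.ival(ch)
        self.counters.bwt_real += 1
        ival = self.index.extend_forward(t.ival(h), b)
        ch = t.new_node(h, b, ival)
        return ch, ival

    fwd_extend = forward_query

    # -- backward trie -------------------------------------------------------

    def backward_insert(self, read: np.ndarray, qbeg: int, qend: int,
                        ival: BiInterval) -> int:
        """Insert the match string read[qbeg:qend) in reverse character order.

        Interior nodes created on the way have unknown intervals; the
        terminal node's interval is set from the forward stage.  No FM-index
        access happens here.
        """
        t = self.bwd
        h = 0
        for i in range(qend - 1, qbeg - 1, -1):
            b = int(read[i])
            ch = t.child[h * 4 + b]
            if ch < 0:
                ch = t.new_node(h, b, None)
            h = ch
        if not t.known(h):
            t.set_ival(h, ival)
        return h

    bwd_init = backward_insert

    def _fill(self, h: int) -> None:
        """Resolve an unknown node top-down from its nearest known ancestor."""
        t = self.bwd
        path = []
        g = h
        while not t.known(g):
            path.append(g)
            g = t.parent[g]
        for node in reversed(path):
            self.counters.bwt_real += 1
            ival = self.index.extend_backward(t.ival(t.parent[node]),
                                              t.pbase[node])
            t.set_ival(node, ival)

    def backward_query(self, h: int, b: int) -> tuple[int, BiInterval]:
        """Child of backward-trie node h along base b (the interval of bP)."""
        self.counters.bwt_queries += 1
        t = self.bwd
        if not t.known(h):
            self._fill(h)
        ch = t.child[h * 4 + b]
        if ch >= 0 and t.known(ch):
            return ch, t.ival(ch)
        self.counters.bwt_real += 1
        ival = self.index.extend_backward(t.ival(h), b)
        if ch < 0:
            ch = t.new_node(h, b, ival)
        else:
            t.set_ival(ch, ival)
        return ch, ival

    bwd_extend = backward_query

    # -- merged SAL ----------------------------------------------------------

    def sal_resolve(self, rank: int) -> int:
        """Per-batch memoized suffix-array lookup."""
        self.counters.sal_queries += 1
        if self.sal_merge:
            p = self._sal_memo.get(rank)
            if p is not None:
                return p
            p = self.index.sal(rank)
            self.counters.sal_real += 1
            self._sal_memo[rank] = p
            return p
        self.counters.sal_real += 1
        return self.index.sal(rank)

    sal = sal_resolve
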