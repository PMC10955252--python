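"""Bidirectional (FMD-style) FM-index over a reference and its reverse complement.

The index supports the two primitives that dominate seeding cost:

* ``extend_backward`` / ``extend_forward`` — BWT-extend: from the bi-interval
  of a pattern P, compute the bi-interval of bP or Pb in O(1) checkpointed
  occurrence lookups.
* ``sal`` — suffix-array lookup: resolve one rank of an interval to a text
  position via the sampled suffix array and LF-stepping.

Layout: every N-free segment of the reference (records are concatenated,
then split at runs of N) is appended to the text S followed by a sentinel;
the reverse complements of all segments follow, each with its own sentinel.
A pattern over {A,C,G,T} therefore never matches across a segment boundary,
and its interval size equals its occurrence count on the forward strand plus
the occurrence count of its reverse complement (both counted on the original
reference).
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from . import _kernels

INDEX_FORMAT_VERSION = 1

#: base codes: A=0 C=1 G=2 T=3, anything else (incl. N) = 4
CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    CODE[ord(_ch)] = _i
    CODE[ord(_ch.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> 4)."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


class IndexError_(ValueError):
    """Raised for unindexable references or corrupted index files."""


@dataclass(frozen=True)
class Reference:
    """A named reference sequence over the A/C/G/T/N alphabet."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise IndexError_(f"reference {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


class BiInterval(NamedTuple):
    """Bidirectional suffix-array interval of a pattern P.

    ``k`` is the first SA rank of P, ``l`` the first rank of revcomp(P), and
    ``s`` the interval size (number of occurrences of P in the doubled text).
    """

    k: int
    l: int
    s: int


def suffix_array(keys: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (numpy lexsort)."""
    n = keys.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(keys, return_inverse=True)
    rank = rank.astype(np.int64)
    step = 1
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - step] = rank[step:]
        order = np.lexsort((rank2, rank))
        r1 = rank[order]
        r2 = rank2[order]
        bumped = np.empty(n, dtype=np.int64)
        bumped[0] = 0
        bumped[1:] = (np.diff(r1) != 0) | (np.diff(r2) != 0)
        new_sorted = np.cumsum(bumped)
        if new_sorted[-1] == n - 1:
            return order
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_sorted
        step *= 2


def _segments(refs: Sequence[Reference]):
    """Yield (global_ref_offset, segment_string) for N-free stretches."""
    off = 0
    for ref in refs:
        codes = encode(ref.seq)
        n = codes.size
        i = 0
        while i < n:
            if codes[i] == 4:
                i += 1
                continue
            j = i
            while j < n and codes[j] != 4:
                j += 1
            yield off + i, ref.seq[i:j].upper()
            i = j
        off += n


class FmdIndex:
    """FM-index of reference + reverse complement with sampled SA."""

    def __init__(self, *, bwt, ck, cum, samp, counts, n, nsent,
                 sa_sample_interval, st_start, st_len, st_ref_off, st_is_rc,
                 names, record_starts, ref_len):
        self.bwt = bwt
        self.ck = ck
        self.cum = cum
        self.samp = samp
        self.counts = counts
        self.n = int(n)
        self.nsent = int(nsent)
        self.sa_sample_interval = int(sa_sample_interval)
        self.st_start = st_start
        self.st_len = st_len
        self.st_ref_off = st_ref_off
        self.st_is_rc = st_is_rc
        self.names = list(names)
        self.record_starts = record_starts
        self.ref_len = int(ref_len)

    # -- intervals -----------------------------------------------------------

    def empty_interval(self) -> BiInterval:
        return BiInterval(0, 0, self.n)

    def base_interval(self, b: int) -> BiInterval:
        """Bi-interval of the single base b, read off the cumulative counts."""
        return BiInterval(int(self.cum[b]), int(self.cum[3 - b]),
                          int(self.counts[b]))

    def extend_backward(self, ival: BiInterval, b: int) -> BiInterval:
        """Bi-interval of bP from the bi-interval of P."""
        k, l, s = _kernels.extend_backward(self.bwt, self.ck, self.cum,
                                           ival.k, ival.l, ival.s, b)
        return BiInterval(k, l, s)

    def extend_forward(self, ival: BiInterval, b: int) -> BiInterval:
        """Bi-interval of Pb: backward extension on the reverse-complement side."""
        k, l, s = _kernels.extend_backward(self.bwt, self.ck, self.cum,
                                           ival.l, ival.k, ival.s, 3 - b)
        return BiInterval(l, k, s)

    def pattern_interval(self, pattern: str) -> BiInterval:
        """Interval of a full pattern by chained backward extensions."""
        codes = encode(pattern)
        if codes.size == 0 or (codes == 4).any():
            raise ValueError("pattern must be non-empty and over ACGT")
        ival = self.base_interval(int(codes[-1]))
        for b in codes[-2::-1]:
            ival = self.extend_backward(ival, int(b))
            if ival.s == 0:
                break
        return ival

    # -- suffix-array lookup -------------------------------------------------

    def sal(self, rank: int) -> int:
        """Text position (in the doubled text S) of the rank-th suffix."""
        if not 0 <= rank < self.n:
            raise IndexError_(f"SA rank {rank} out of range [0, {self.n})")
        return int(_kernels.sal(self.bwt, self.ck, self.cum, self.samp, rank))

    def position(self, p: int, length: int) -> tuple[int, str]:
        """Map text position p of a `length`-base match to reference coordinates.

        Returns the forward-strand leftmost 0-based position (concatenated
        across records) and the strand.
        """
        si = int(np.searchsorted(self.st_start, p, side="right")) - 1
        if si < 0 or p + length > self.st_start[si] + self.st_len[si]:
            raise IndexError_("match spans a segment boundary")
        off = p - int(self.st_start[si])
        if self.st_is_rc[si]:
            rbeg = int(self.st_ref_off[si]) + int(self.st_len[si]) - off - length
            return rbeg, "-"
        return int(self.st_ref_off[si]) + off, "+"

    def locate(self, rank: int, length: int) -> tuple[int, str]:
        """Reference position and strand of the match whose interval holds `rank`."""
        return self.position(self.sal(rank), length)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format_version": INDEX_FORMAT_VERSION,
            "n": self.n,
            "nsent": self.nsent,
            "sa_sample_interval": self.sa_sample_interval,
            "names": self.names,
            "ref_len": self.ref_len,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            bwt=self.bwt, ck=self.ck, cum=self.cum, samp=self.samp,
            counts=self.counts, st_start=self.st_start, st_len=self.st_len,
            st_ref_off=self.st_ref_off, st_is_rc=self.st_is_rc,
            record_starts=self.record_starts,
        )

    @classmethod
    def load(cls, path) -> "FmdIndex":
        try:
            with np.load(path) as z:
                meta = json.loads(z["meta"].tobytes().decode())
                if meta.get("format_version") != INDEX_FORMAT_VERSION:
                    raise IndexError_(
                        f"unsupported index format {meta.get('format_version')!r}")
                return cls(
                    bwt=z["bwt"], ck=z["ck"], cum=z["cum"], samp=z["samp"],
                    counts=z["counts"], n=meta["n"], nsent=meta["nsent"],
                    sa_sample_interval=meta["sa_sample_interval"],
                    st_start=z["st_start"], st_len=z["st_len"],
                    st_ref_off=z["st_ref_off"], st_is_rc=z["st_is_rc"],
                    names=meta["names"], record_starts=z["record_starts"],
                    ref_len=meta["ref_len"],
                )
        except IndexError_:
            raise
        except Exception as exc:  # zip/json/key errors -> fail closed
            raise IndexError_(f"cannot load index from {path!r}: {exc}") from exc


def build_index(ref: Reference | Sequence[Reference],
                sa_sample_interval: int = 32) -> FmdIndex:
    """Build the FMD-style index of one or more reference records.

    Records are concatenated in a single 0-based coordinate space; N runs are
    excluded from the text (seeds never span them).  ``sa_sample_interval``
    controls suffix-array sparsity: position p is sampled iff p % d == 0, p
    starts a segment, or p is a sentinel.
    """
    if sa_sample_interval < 1:
        raise ValueError("sa_sample_interval must be >= 1")
    refs = [ref] if isinstance(ref, Reference) else list(ref)
    if not refs:
        raise IndexError_("no reference records given")
    segs = list(_segments(refs))
    if not segs:
        raise IndexError_("reference contains no indexable A/C/G/T bases")

    record_starts = np.cumsum([0] + [len(r.seq) for r in refs[:-1]]).astype(np.int64)
    ref_len = sum(len(r.seq) for r in refs)

    parts: list[np.ndarray] = []
    st_start, st_len, st_ref_off, st_is_rc = [], [], [], []
    pos = 0
    nsent = 0
    sentinel = 4  # class code; sentinels get distinct sort keys below

    def _append(codes: np.ndarray, ref_off: int, is_rc: bool) -> None:
        nonlocal pos, nsent
        st_start.append(pos)
        st_len.append(codes.size)
        st_ref_off.append(ref_off)
        st_is_rc.append(is_rc)
        parts.append(codes)
        parts.append(np.array([sentinel], dtype=np.uint8))
        pos += codes.size + 1
        nsent += 1

    for off, seq in segs:
        _append(encode(seq), off, False)
    for off, seq in reversed(segs):
        _append(encode(revcomp(seq)), off, True)

    s_codes = np.concatenate(parts)
    n = s_codes.size

    # distinct sort keys: j-th sentinel -> j, base b -> nsent + b
    sort_keys = s_codes.astype(np.int64) + nsent
    sent_pos = np.flatnonzero(s_codes == sentinel)
    sort_keys[sent_pos] = np.arange(nsent)

    sa = suffix_array(sort_keys)
    bwt = s_codes[(sa - 1) % n]
    ck = _kernels.build_checkpoints(bwt)
    counts = np.bincount(s_codes, minlength=5).astype(np.int64)
    cum = np.empty(4, dtype=np.int64)
    cum[0] = nsent
    for c in range(1, 4):
        cum[c] = cum[c - 1] + counts[c - 1]

    seg_start_mask = np.zeros(n, dtype=bool)
    seg_start_mask[np.array(st_start, dtype=np.int64)] = True
    sampled_pos = (sa % sa_sample_interval == 0) | (s_codes[sa] == sentinel) \
        | seg_start_mask[sa]
    samp = np.where(sampled_pos, sa, -1).astype(np.int64)

    return FmdIndex(
        bwt=bwt, ck=ck, cum=cum, samp=samp, counts=counts[:4], n=n,
        nsent=nsent, sa_sample_interval=sa_sample_interval,
        st_start=np.array(st_start, dtype=np.int64),
        st_len=np.array(st_len, dtype=np.int64),
        st_ref_off=np.array(st_ref_off, dtype=np.int64),
        st_is_rc=np.array(st_is_rc, dtype=bool),
        names=[r.name for r in refs], record_starts=record_starts,
        ref_len=ref_len,
    )
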