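"""Hot inner loops of the FM-index, compiled with numba.

The BWT is stored as uint8 class codes 0..4 (A, C, G, T, sentinel class).
Occurrence counts are checkpointed every 128 BWT positions; each primitive
scans at most one partial block per boundary.
"""
from __future__ import annotations

import numba as nb
import numpy as np

CKPT_SHIFT = 7  # checkpoint every 128 positions
CKPT_STEP = 1 << CKPT_SHIFT


@nb.njit(nb.int64[:, :](nb.uint8[:]), cache=True)
def build_checkpoints(bwt):
    n = bwt.size
    nblk = (n >> CKPT_SHIFT) + 1
    ck = np.zeros((nblk, 5), dtype=np.int64)
    for blk in range(1, nblk):
        for c in range(5):
            ck[blk, c] = ck[blk - 1, c]
        for i in range((blk - 1) << CKPT_SHIFT, blk << CKPT_SHIFT):
            ck[blk, bwt[i]] += 1
    return ck


@nb.njit(nb.types.UniTuple(nb.int64, 3)(
    nb.uint8[:], nb.int64[:, :], nb.int64[:],
    nb.int64, nb.int64, nb.int64, nb.int64), cache=True)
def extend_backward(bwt, ck, cum, k, l, s, b):
    """Bi-interval of b+P given the bi-interval (k, l, s) of P.

    `cum[c]` is the SA index where the block of suffixes starting with base c
    begins (sentinels sort first).  The reverse-complement side [l, l+s) is
    tiled in the order sentinel, T, G, C, A, mirroring the complement order of
    the appended character on that side.
    """
    e = k + s
    blk = k >> CKPT_SHIFT
    a0 = ck[blk, 0]; a1 = ck[blk, 1]; a2 = ck[blk, 2]
    a3 = ck[blk, 3]; a4 = ck[blk, 4]
    for i in range(blk << CKPT_SHIFT, k):
        c = bwt[i]
        if c == 0:
            a0 += 1
        elif c == 1:
            a1 += 1
        elif c == 2:
            a2 += 1
        elif c == 3:
            a3 += 1
        else:
            a4 += 1
    blk = e >> CKPT_SHIFT
    b0 = ck[blk, 0]; b1 = ck[blk, 1]; b2 = ck[blk, 2]
    b3 = ck[blk, 3]; b4 = ck[blk, 4]
    for i in range(blk << CKPT_SHIFT, e):
        c = bwt[i]
        if c == 0:
            b0 += 1
        elif c == 1:
            b1 += 1
        elif c == 2:
            b2 += 1
        elif c == 3:
            b3 += 1
        else:
            b4 += 1
    s0 = b0 - a0; s1 = b1 - a1; s2 = b2 - a2; s3 = b3 - a3
    sent = b4 - a4
    if b == 0:
        return cum[0] + a0, l + sent + s3 + s2 + s1, s0
    elif b == 1:
        return cum[1] + a1, l + sent + s3 + s2, s1
    elif b == 2:
        return cum[2] + a2, l + sent + s3, s2
    else:
        return cum[3] + a3, l + sent, s3


@nb.njit(nb.int64(nb.uint8[:], nb.int64[:, :], nb.int64[:], nb.int64[:],
                  nb.int64), cache=True)
def sal(bwt, ck, cum, samp, r):
    """Text position of the rank-r suffix, by LF-stepping to a sampled rank.

    `samp[r]` is the suffix position if rank r is sampled, else -1.  Every
    rank whose BWT character is a sentinel is sampled at build time, so the
    walk never needs an LF step across a segment boundary.
    """
    t = 0
    while samp[r] < 0:
        c = bwt[r]
        blk = r >> CKPT_SHIFT
        o = ck[blk, c]
        for i in range(blk << CKPT_SHIFT, r):
            if bwt[i] == c:
                o += 1
        r = cum[c] + o
        t += 1
    return samp[r] + t
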