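"""Synthetic genomes and reordered read sets.

The generator produces the input structure the trie cache exploits: short
substitution-error reads at a chosen fold coverage, optionally laid out the
way reordering-based FASTQ compressors emit them — strand-corrected and
approximately sorted by genomic position, so that consecutive reads share
large overlaps.  The ``oracle`` reorder mode uses the simulation truth (the
idealized compressor); the ``minimizer`` mode is reference-free and buckets
reads by their lexicographically smallest k-mer over both strands.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .fmindex import Reference, decode, encode, revcomp

_MINIMIZER_K = 12


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    genome_length: int = 100_000
    repeat_count: int = 0       # planted duplicate segments
    repeat_length: int = 0
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.005   # per-base substitution probability
    revcomp_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if self.repeat_count and self.repeat_length > self.genome_length:
            raise ValueError("repeat_length exceeds genome_length")


class SimRead(NamedTuple):
    read_id: str
    seq: str
    true_pos: int
    true_strand: str


def simulate_genome(cfg: SimConfig) -> Reference:
    """I.i.d. uniform ACGT genome with optional planted repeat copies.

    A single source segment of ``repeat_length`` bases is copied to
    ``repeat_count - 1`` random positions (so the segment occurs at least
    ``repeat_count`` times), overwriting the background sequence.
    Deterministic for a given rng_seed.
    """
    rng = np.random.default_rng([cfg.rng_seed, 0])
    codes = rng.integers(0, 4, size=cfg.genome_length, dtype=np.uint8)
    if cfg.repeat_count > 0 and cfg.repeat_length > 0:
        src = int(rng.integers(0, cfg.genome_length - cfg.repeat_length + 1))
        segment = codes[src:src + cfg.repeat_length].copy()
        for _ in range(cfg.repeat_count - 1):
            dst = int(rng.integers(0, cfg.genome_length - cfg.repeat_length + 1))
            codes[dst:dst + cfg.repeat_length] = segment
    return Reference("sim", decode(codes))


def simulate_reads(ref: Reference, cfg: SimConfig) -> list[SimRead]:
    """Uniform-position reads with substitution errors and random strand.

    n = round(coverage * L / read_length) reads; each base is substituted
    with probability error_rate (always to a different base); the read is
    reverse-complemented with probability revcomp_fraction.  true_pos is the
    forward-strand leftmost position.
    """
    rng = np.random.default_rng([cfg.rng_seed, 1])
    L, rl = len(ref.seq), cfg.read_length
    n = int(round(cfg.coverage * L / rl))
    genome = encode(ref.seq)
    starts = rng.integers(0, L - rl + 1, size=n)
    flip = rng.random(n) < cfg.revcomp_fraction
    err = rng.random((n, rl)) < cfg.error_rate
    shift = rng.integers(1, 4, size=(n, rl), dtype=np.uint8)
    reads = []
    for i in range(n):
        codes = genome[starts[i]:starts[i] + rl].copy()
        e = err[i]
        if e.any():
            codes[e] = (codes[e] + shift[i][e]) % 4
        seq = decode(codes)
        strand = "-" if flip[i] else "+"
        if flip[i]:
            seq = revcomp(seq)
        reads.append(SimRead(f"r{i}", seq, int(starts[i]), strand))
    return reads


ReorderMode = Literal["oracle", "minimizer", "none"]


def reorder_reads(reads: Sequence[SimRead],
                  mode: ReorderMode = "oracle") -> list[SimRead]:
    """Rearrange reads the way a reordering-based compressor would.

    oracle     strand-normalize to forward orientation and sort by the true
               position (requires simulation truth);
    minimizer  reference-free: orient each read so its smallest k-mer over
               both strands reads forward, bucket by that k-mer, order
               buckets lexicographically and stack reads within a bucket by
               minimizer offset descending;
    none       keep the input order.
    """
    if mode == "none":
        return list(reads)
    if mode == "oracle":
        norm = [r if r.true_strand == "+" else
                SimRead(r.read_id, revcomp(r.seq), r.true_pos, "+")
                for r in reads]
        return sorted(norm, key=lambda r: (r.true_pos, r.read_id))
    if mode == "minimizer":
        keyed = []
        for r in reads:
            oriented, kmer, off = _canonical_minimizer(r.seq)
            keyed.append(((kmer, -off, r.read_id),
                          SimRead(r.read_id, oriented, r.true_pos,
                                  r.true_strand)))
        return [r for _, r in sorted(keyed, key=lambda t: t[0])]
    raise ValueError(f"unknown reorder mode {mode!r}")


def _canonical_minimizer(seq: str, k: int = _MINIMIZER_K) -> tuple[str, str, int]:
    """Orient `seq` so its smallest k-mer lies on the forward strand.

    Returns (oriented sequence, minimizer k-mer, minimizer offset in the
    oriented sequence).  Reads shorter than k are left as-is with the whole
    read as key.
    """
    if len(seq) < k:
        return seq, seq, 0
    best = None
    for oriented in (seq, revcomp(seq)):
        for i in range(len(oriented) - k + 1):
            kmer = oriented[i:i + k]
            if best is None or kmer < best[1]:
                best = (oriented, kmer, i)
    return best


def shuffle_reads(reads: Sequence[SimRead], rng_seed: int) -> list[SimRead]:
    """Deterministic random permutation (the FASTQ-order ablation)."""
    rng = np.random.default_rng([rng_seed, 2])
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]
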