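"""Batch seeding driver shared by the CLI, the experiments and the tests."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .fmindex import FmdIndex
from .seeding import DirectAccessor, Seed, SeedingParams, seed_sequence
from .sstcache import OpCounters, SstAccessor

log = logging.getLogger("sstseed")

_VALID = set("ACGTNacgtn")

SEED_TSV_HEADER = "read_id\tqbeg\tqend\tstrand\trbeg\tinterval_size\torigin"


@dataclass
class SeedingRun:
    """Seeds and operation counters of one pass over a read set."""

    seeds: list[tuple[str, list[Seed]]]
    counters: OpCounters
    n_reads: int
    params: SeedingParams
    cache: bool
    sal_merge: bool

    def tsv_lines(self) -> Iterable[str]:
        yield SEED_TSV_HEADER
        for read_id, seeds in self.seeds:
            for s in seeds:
                yield (f"{read_id}\t{s.qbeg}\t{s.qend}\t{s.strand}\t"
                       f"{s.rbeg}\t{s.interval_size}\t{s.origin}")

    def stats(self) -> dict:
        c = self.counters
        n = max(self.n_reads, 1)
        return {
            "n_reads": self.n_reads,
            "cache": self.cache,
            "sal_merge": self.sal_merge,
            "params": {
                "min_intv": self.params.min_intv,
                "min_seed_len": self.params.min_seed_len,
                "reseed_factor": self.params.reseed_factor,
                "max_occ": self.params.max_occ,
                "batch_size": self.params.batch_size,
            },
            "totals": c.to_dict(),
            "per_read": {
                "bwt_queries": c.bwt_queries / n,
                "bwt_real": c.bwt_real / n,
                "sal_queries": c.sal_queries / n,
                "sal_real": c.sal_real / n,
            },
        }


def make_accessor(index: FmdIndex, params: SeedingParams, cache: bool = True,
                  sal_merge: bool = True,
                  counters: Optional[OpCounters] = None):
    if cache:
        return SstAccessor(index, counters=counters,
                           batch_size=params.batch_size, sal_merge=sal_merge)
    return DirectAccessor(index, counters=counters)


def seed_reads(index: FmdIndex, reads: Iterable[tuple[str, str]],
               params: Optional[SeedingParams] = None, cache: bool = True,
               sal_merge: bool = True) -> SeedingRun:
    """Seed a stream of (read_id, sequence) pairs.

    Reads containing characters outside A/C/G/T/N are skipped with a
    warning.  With ``cache`` the trie accessor is used (reset every
    ``params.batch_size`` reads); the seed output is identical either way.
    """
    params = params or SeedingParams()
    acc = make_accessor(index, params, cache=cache, sal_merge=sal_merge)
    out: list[tuple[str, list[Seed]]] = []
    n = 0
    for read_id, seq in reads:
        if not set(seq) <= _VALID:
            log.warning("read %s contains non-ACGTN characters; skipped", read_id)
            continue
        acc.start_read()
        out.append((read_id, seed_sequence(seq, params, acc, index)))
        n += 1
    return SeedingRun(seeds=out, counters=acc.counters, n_reads=n,
                      params=params, cache=cache, sal_merge=sal_merge)
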