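"""Desk-scale experiments: operation-redundancy measurements and parameter sweeps."""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .fmindex import Reference, build_index
from .pipeline import SeedingRun, seed_reads
from .seeding import SeedingParams
from .simulate import SimConfig, reorder_reads, shuffle_reads, simulate_genome, \
    simulate_reads


@dataclass
class RedundancyResult:
    """Cached vs. uncached operation counts on one simulated dataset."""

    n_reads: int
    uncached: SeedingRun
    cached: SeedingRun

    @property
    def bwt_reduction_pct(self) -> float:
        u = self.uncached.counters.bwt_real
        return 100.0 * (1.0 - self.cached.counters.bwt_real / u) if u else 0.0

    @property
    def sal_reduction_pct(self) -> float:
        u = self.uncached.counters.sal_real
        return 100.0 * (1.0 - self.cached.counters.sal_real / u) if u else 0.0

    @property
    def combined_reduction_pct(self) -> float:
        """100 * (1 - real ops cached / real ops uncached), BWT-extend + SAL."""
        u = self.uncached.counters.real_ops
        return 100.0 * (1.0 - self.cached.counters.real_ops / u) if u else 0.0

    def identical_seeds(self) -> bool:
        return list(self.uncached.tsv_lines()) == list(self.cached.tsv_lines())


def _dataset(cfg: SimConfig, order: str):
    ref = simulate_genome(cfg)
    reads = simulate_reads(ref, cfg)
    if order == "shuffled":
        reads = shuffle_reads(reads, cfg.rng_seed)
    else:
        reads = reorder_reads(reads, order)
    return ref, [(r.read_id, r.seq) for r in reads]


def redundancy_experiment(cfg: SimConfig,
                          params: Optional[SeedingParams] = None,
                          order: str = "oracle",
                          index=None) -> RedundancyResult:
    """Run seeding twice (direct FM-index, then trie cache + merged SAL) on
    one simulated, reordered read set and compare real operation counts."""
    params = params or SeedingParams()
    ref, reads = _dataset(cfg, order)
    if index is None:
        index = build_index(ref)
    uncached = seed_reads(index, reads, params, cache=False)
    cached = seed_reads(index, reads, params, cache=True, sal_merge=True)
    return RedundancyResult(n_reads=uncached.n_reads, uncached=uncached,
                            cached=cached)


def coverage_sweep(base_cfg: SimConfig,
                   coverages: Sequence[float] = (5, 10, 20, 40),
                   params: Optional[SeedingParams] = None,
                   include_uncached: bool = True) -> list[dict]:
    """Per-read real-access averages of the cached path across coverages.

    Reuses one genome and index; each grid point draws its own reads at the
    requested fold coverage, oracle-reordered.
    """
    params = params or SeedingParams()
    genome_cfg = replace(base_cfg, coverage=coverages[0])
    ref = simulate_genome(genome_cfg)
    index = build_index(ref)
    rows = []
    for cov in coverages:
        cfg = replace(base_cfg, coverage=float(cov))
        reads = [(r.read_id, r.seq)
                 for r in reorder_reads(simulate_reads(ref, cfg), "oracle")]
        cached = seed_reads(index, reads, params, cache=True)
        row = {
            "coverage": float(cov),
            "n_reads": cached.n_reads,
            "cached_real_per_read":
                cached.counters.real_ops / max(cached.n_reads, 1),
            "cached_bwt_real_per_read":
                cached.counters.bwt_real / max(cached.n_reads, 1),
            "cached_sal_real_per_read":
                cached.counters.sal_real / max(cached.n_reads, 1),
        }
        if include_uncached:
            uncached = seed_reads(index, reads, params, cache=False)
            u = uncached.counters
            row["uncached_real_per_read"] = u.real_ops / max(uncached.n_reads, 1)
            row["reduction_pct"] = 100.0 * (
                1.0 - cached.counters.real_ops / u.real_ops) if u.real_ops else 0.0
        rows.append(row)
    return rows


def reseed_sweep(base_cfg: SimConfig,
                 r_values: Sequence[float] = (1.5, 1.3, 1.1),
                 params: Optional[SeedingParams] = None,
                 include_uncached: bool = False) -> list[dict]:
    """Effect of relaxing the re-seeding trigger -r on cached real accesses.

    Queries issued are identical with and without the cache, so the query
    totals of the cached run stand in for the uncached workload.
    """
    params = params or SeedingParams()
    ref, reads = _dataset(base_cfg, "oracle")
    index = build_index(ref)
    rows = []
    for r in r_values:
        p = replace(params, reseed_factor=float(r))
        cached = seed_reads(index, reads, p, cache=True)
        c = cached.counters
        row = {
            "reseed_factor": float(r),
            "n_reads": cached.n_reads,
            "queries": c.queries,
            "cached_real": c.real_ops,
            "queries_per_read": c.queries / max(cached.n_reads, 1),
            "cached_real_per_read": c.real_ops / max(cached.n_reads, 1),
        }
        if include_uncached:
            uncached = seed_reads(index, reads, p, cache=False)
            row["uncached_real"] = uncached.counters.real_ops
        rows.append(row)
    return rows
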