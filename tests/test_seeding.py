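"""SMEM search against brute-force enumeration, plus seed materialization."""
import numpy as np
import pytest

from sstseed import (DirectAccessor, Reference, SeedingParams, SimConfig,
                     build_index, collect_smems, materialize_seeds, reseed,
                     revcomp, seed_reads, simulate_genome, simulate_reads,
                     super_mem1)
from sstseed.fmindex import encode
from sstseed.seeding import seed_sequence

from _oracles import SubstringCounter, smem_set
from conftest import random_seq


def _acc(index):
    return DirectAccessor(index)


def test_params_validation():
    with pytest.raises(ValueError):
        SeedingParams(min_intv=0)
    with pytest.raises(ValueError):
        SeedingParams(reseed_factor=1.0)


@pytest.mark.parametrize("inst", range(4))
def test_super_mem1_equals_bruteforce_at_every_pivot(inst):
    """SuperMEM1 returns exactly the pivot-covering maximal matches."""
    cfg = SimConfig(genome_length=1500, coverage=1, read_length=80,
                    error_rate=0.03, repeat_count=3 if inst % 2 else 0,
                    repeat_length=50, rng_seed=200 + inst)
    ref = simulate_genome(cfg)
    idx = build_index(ref)
    counter = SubstringCounter(ref.seq)
    acc = _acc(idx)
    for read in simulate_reads(ref, cfg)[:3]:
        codes = encode(read.seq)
        for pivot in range(len(read.seq)):
            got = {(m.qbeg, m.qend)
                   for m in super_mem1(codes, pivot, 1 + inst % 2, acc)}
            assert got == smem_set(counter, read.seq, 1 + inst % 2, pivot=pivot)


def test_unique_read_gives_single_whole_read_smem():
    seq = random_seq(5, 2000)
    idx = build_index(Reference("g", seq))
    read = seq[700:750]
    mems = super_mem1(encode(read), 0, 1, _acc(idx))
    assert [(m.qbeg, m.qend) for m in mems] == [(0, 50)]
    assert mems[0].ival.s == 1


def test_dead_pivot_returns_empty():
    idx = build_index(Reference("a", "A" * 200))
    read = "A" * 10 + "C" + "A" * 10
    assert super_mem1(encode(read), 10, 1, _acc(idx)) == []


def test_substitution_splits_unique_read_into_flanking_smems():
    seq = random_seq(6, 3000)
    idx = build_index(Reference("g", seq))
    read = seq[1000:1100]
    bad = "ACGT"[("ACGT".index(read[50]) + 1) % 4]
    read = read[:50] + bad + read[51:]
    params = SeedingParams(min_seed_len=19)
    smems = collect_smems(encode(read), params, _acc(idx))
    counter = SubstringCounter(seq)
    assert {(m.qbeg, m.qend) for m in smems} == \
        smem_set(counter, read, 1, min_len=19)
    assert {(m.qbeg, m.qend) for m in smems} == {(0, 50), (51, 100)}


def test_collect_smems_equals_bruteforce_with_repeats():
    cfg = SimConfig(genome_length=2000, coverage=2, read_length=100,
                    error_rate=0.01, repeat_count=4, repeat_length=70,
                    rng_seed=31)
    ref = simulate_genome(cfg)
    idx = build_index(ref)
    counter = SubstringCounter(ref.seq)
    params = SeedingParams(min_seed_len=15)
    acc = _acc(idx)
    for read in simulate_reads(ref, cfg)[:20]:
        got = {(m.qbeg, m.qend)
               for m in collect_smems(encode(read.seq), params, acc)}
        assert got == smem_set(counter, read.seq, 1, min_len=15)


def test_reseed_trigger_and_raised_threshold():
    """Re-seeding fires only above min_seed_len * r and searches at the SMEM
    middle with min-intv raised past the SMEM's occurrence count."""
    cfg = SimConfig(genome_length=2000, coverage=0.1, read_length=80,
                    error_rate=0.0, repeat_count=3, repeat_length=60,
                    rng_seed=77)
    ref = simulate_genome(cfg)
    idx = build_index(ref)
    counter = SubstringCounter(ref.seq)
    params = SeedingParams(min_seed_len=19, reseed_factor=1.5)
    acc = _acc(idx)
    assert params.reseed_factor == 1.5  # default trigger ratio
    triggered = 0
    for read in simulate_reads(ref, cfg):
        for m in collect_smems(encode(read.seq), params, acc):
            out = reseed(m, encode(read.seq), params, acc)
            if m.length < params.min_seed_len * params.reseed_factor:
                assert out == []
                continue
            triggered += 1
            mid = (m.qbeg + m.qend) // 2
            assert {(x.qbeg, x.qend) for x in out} == \
                smem_set(counter, read.seq, m.ival.s + 1, min_len=19, pivot=mid)
    assert triggered > 0


def test_materialize_caps_at_max_occ(index500, ref500):
    params = SeedingParams(min_seed_len=1, max_occ=2)
    acc = _acc(index500)
    # a single base occurs far more than twice -> skipped entirely
    big = super_mem1(encode("A"), 0, 1, acc)
    assert big and big[0].ival.s > 2
    assert materialize_seeds([(big[0], "smem")], params, acc, index500) == []
    # a unique 30-mer -> exactly one seed at the right position
    read = ref500.seq[100:130]
    m = super_mem1(encode(read), 0, 1, acc)[0]
    seeds = materialize_seeds([(m, "smem")], params, acc, index500)
    assert len(seeds) == 1
    assert (seeds[0].rbeg, seeds[0].strand) == (100, "+")


def test_seeds_match_reference_substrings(small_sim):
    """Every emitted seed is an exact, strand-aware reference match."""
    cfg, ref, reads, idx = small_sim
    run = seed_reads(idx, [(r.read_id, r.seq) for r in reads[:300]],
                     SeedingParams(), cache=False)
    by_id = {r.read_id: r.seq for r in reads}
    checked = 0
    for read_id, seeds in run.seeds:
        for s in seeds:
            sub = by_id[read_id][s.qbeg:s.qend]
            refsub = ref.seq[s.rbeg:s.rbeg + s.length]
            assert sub == (refsub if s.strand == "+" else revcomp(refsub))
            checked += 1
    assert checked > 300


def test_seeding_is_deterministic(small_sim):
    cfg, ref, reads, idx = small_sim
    pairs = [(r.read_id, r.seq) for r in reads[:100]]
    a = list(seed_reads(idx, pairs, cache=True).tsv_lines())
    b = list(seed_reads(idx, pairs, cache=True).tsv_lines())
    assert a == b


def test_lower_reseed_factor_never_removes_seeds(small_sim):
    """Relaxing -r only adds re-seeding rounds, so seeds at r=1.2 are a
    superset of those at r=1.5."""
    cfg, ref, reads, idx = small_sim
    pairs = [(r.read_id, r.seq) for r in reads[:150]]
    loose = seed_reads(idx, pairs, SeedingParams(reseed_factor=1.2), cache=False)
    tight = seed_reads(idx, pairs, SeedingParams(reseed_factor=1.5), cache=False)
    loose_set = set(loose.tsv_lines())
    assert loose_set >= set(tight.tsv_lines())


def test_reads_split_at_n():
    seq = random_seq(8, 1000)
    idx = build_index(Reference("g", seq))
    read = seq[100:140] + "N" + seq[300:340]
    seeds = seed_sequence(read, SeedingParams(), _acc(idx), idx)
    spans = {(s.qbeg, s.qend, s.rbeg) for s in seeds}
    assert (0, 40, 100) in spans
    assert (41, 81, 300) in spans
    assert all(not (s.qbeg <= 40 < s.qend) for s in seeds)
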