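"""Orthogonal pooling scheme, barcode demultiplexing and deconvolution."""

from collections import Counter

import pytest

from sgarray import pooling, simulate
from sgarray.pooling import (
    Allocation,
    ConfigError,
    PoolId,
    PoolingScheme,
    WellAddress,
    allocation_report,
    build_scheme,
    deconvolve,
    demultiplex,
    scheme_capacity,
)

from conftest import random_seq


class TestSchemeGeometry:
    def test_one_full_set(self):
        sch = build_scheme(32)
        assert sch.n_sets == 1
        assert len(sch.position_pools(0)) == 96
        assert len(sch.group_pools(0)) == 96
        for pool in sch.position_pools(0) + sch.group_pools(0):
            assert len(sch.pool_members(pool)) == 32

    def test_published_campaign_sets(self):
        assert build_scheme(308).n_sets == 10

    def test_single_plate_degenerate_set(self):
        sch = build_scheme(1)
        assert sch.n_sets == 1
        assert all(len(sch.pool_members(p)) == 1 for p in sch.position_pools(0))
        grp = [p for p in sch.group_pools(0) if sch.pool_members(p)]
        assert len(grp) == 3
        assert all(len(sch.pool_members(p)) == 32 for p in grp)

    def test_well_to_pool_map_is_injective_within_set(self):
        sch = build_scheme(32)
        seen = set()
        for addr in sch.wells():
            pools = sch.pools_of(addr)
            assert pools not in seen
            seen.add(pools)

    def test_every_well_in_exactly_one_pool_of_each_kind(self):
        sch = build_scheme(32)
        membership = Counter()
        for kind_pools in (sch.position_pools(0), sch.group_pools(0)):
            for pool in kind_pools:
                for addr in sch.pool_members(pool):
                    membership[(addr, pool.kind)] += 1
        for addr in sch.wells():
            assert membership[(addr, "position")] == 1
            assert membership[(addr, "group")] == 1

    def test_group_pools_are_4_column_blocks(self):
        sch = build_scheme(32)
        plate, block = sch.group_pool_address("I")
        assert (plate, block) == (0, 0)
        assert sch.group_pool_address("IV") == (1, 0)
        members = sch.pool_members(PoolId(0, "group", "I"))
        assert {m.well for m in members} == {
            f"{r}{c}" for r in "ABCDEFGH" for c in (1, 2, 3, 4)
        }

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigError):
            build_scheme(1, cols=10, block_cols=4)
        with pytest.raises(ConfigError):
            build_scheme(0)


class TestCapacity:
    def test_published_run_parameters(self):
        assert scheme_capacity() == (1152, 18432)

    def test_reduced_first_level(self):
        assert scheme_capacity(n_barcode1=2) == (192, 3072)

    def test_capacity_matches_enumerated_scheme(self):
        """12 x 96 barcode triples enumerate exactly the pools of 6 sets."""
        sch = build_scheme(192)  # 6 sets = one sequencing run
        triples = sch.triple_to_pool(run=0)
        n_pools, n_clones = scheme_capacity()
        assert len(triples) == n_pools
        n_wells = sum(
            sch.plates_in_set(s) * sch.wells_per_plate for s in range(sch.n_sets)
        )
        assert n_wells == n_clones


class TestDemultiplex:
    def test_exact_match_assigned(self):
        sch = build_scheme(1)
        pool = sch.position_pools(0)[0]
        b1, b2, b3 = sch.pool_barcode_triple(pool)
        obs, discarded = demultiplex([b1 + b2 + b3 + "ACGT"], sch.barcodes)
        assert discarded == 0
        assert obs[(b1, b2, b3)]["ACGT"] == 1

    def test_one_mismatch_discarded_in_strict_mode(self):
        sch = build_scheme(1)
        b1, b2, b3 = sch.pool_barcode_triple(sch.position_pools(0)[0])
        mutated = ("A" if b1[0] != "A" else "C") + b1[1:]
        obs, discarded = demultiplex([mutated + b2 + b3 + "ACGT"], sch.barcodes)
        assert discarded == 1 and not obs

    def test_one_mismatch_rescued_at_tolerance_1(self):
        sch = build_scheme(1)
        b1, b2, b3 = sch.pool_barcode_triple(sch.position_pools(0)[0])
        mutated = ("A" if b1[0] != "A" else "C") + b1[1:]
        obs, discarded = demultiplex(
            [mutated + b2 + b3 + "ACGT"], sch.barcodes, max_mismatch=1
        )
        assert discarded == 0 and obs[(b1, b2, b3)]["ACGT"] == 1

    def test_colliding_tables_rejected(self):
        bad = (["AAAAAA", "AAAAAA"], ["ACACAC"], ["GTGTGT"])
        with pytest.raises(ConfigError):
            demultiplex([], bad)

    def test_simulated_run_fully_recovered(self, rng):
        """10,000 error-free reads all land in their true pools."""
        sch = build_scheme(4, plates_per_set=4)
        lib = [random_seq(rng, 20) for _ in range(4 * 96)]
        assign = simulate.arrange_in_plates([(f"m{i}", s) for i, s in enumerate(lib)], sch)
        # ~10k reads: 4*96 wells x 2 pools x depth 13
        reads, _ = simulate.simulate_pool_reads(assign, sch, depth=13, seed=0)
        obs, discarded = demultiplex(reads, sch.barcodes)
        assert discarded == 0
        truth = Counter()
        for addr, (_, spacer) in assign.items():
            for pool in sch.pools_of(addr):
                truth[(sch.pool_barcode_triple(pool), spacer)] += 13
        got = Counter(
            ((triple, spacer), n)
            for triple, counts in obs.items() for spacer, n in counts.items()
        )
        assert {k: v for (k, v) in got} == dict(truth)


def _observation_for(sch, pool, spacer, count=100):
    return sch.pool_barcode_triple(pool), Counter({spacer: count})


class TestDeconvolve:
    def test_consistent_pair_gives_unique_well(self):
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        # position pool B3 + group pool of (plate 2, columns 1-4)
        grp_label = sch.group_label(1, 0)  # plate index 1 = plate 2
        obs = dict(
            [
                _observation_for(sch, PoolId(0, "position", "B3"), spacer),
                _observation_for(sch, PoolId(0, "group", grp_label), spacer),
            ]
        )
        allocs, _ = deconvolve(obs, sch, [spacer])
        (a,) = allocs
        assert a.status == "unique"
        assert a.address == WellAddress(0, 1, "B3")

    def test_duplicate_clone_same_well_two_plates_is_ambiguous(self):
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        obs = dict(
            [
                _observation_for(sch, PoolId(0, "position", "A1"), spacer, 200),
                _observation_for(sch, PoolId(0, "group", sch.group_label(0, 0)), spacer),
                _observation_for(sch, PoolId(0, "group", sch.group_label(4, 0)), spacer),
            ]
        )
        allocs, _ = deconvolve(obs, sch, [spacer])
        (a,) = allocs
        assert a.status == "ambiguous"
        assert len(a.candidates) == 2

    def test_group_only_evidence_is_absent(self):
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        obs = dict([_observation_for(sch, PoolId(0, "group", "I"), spacer)])
        allocs, _ = deconvolve(obs, sch, [spacer])
        assert allocs[0].status == "absent"

    def test_mismatched_column_blocks_are_inconsistent(self):
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        # position pool in column 9 vs group pool covering columns 1-4
        obs = dict(
            [
                _observation_for(sch, PoolId(0, "position", "A9"), spacer),
                _observation_for(sch, PoolId(0, "group", sch.group_label(0, 0)), spacer),
            ]
        )
        allocs, _ = deconvolve(obs, sch, [spacer])
        assert allocs[0].status == "inconsistent"

    def test_non_library_spacers_reported_as_synthesis_errors(self):
        sch = build_scheme(32)
        member = "ACGT" * 5
        mutant = "TCGT" * 5
        triple = sch.pool_barcode_triple(PoolId(0, "position", "A1"))
        obs = {triple: Counter({member: 50, mutant: 50})}
        allocs, errors = deconvolve(obs, sch, [member])
        assert errors[mutant] == 50
        assert all(a.spacer != mutant for a in allocs)

    def test_below_threshold_reads_do_not_count(self):
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        obs = dict(
            [
                _observation_for(sch, PoolId(0, "position", "B3"), spacer, count=3),
                _observation_for(sch, PoolId(0, "group", sch.group_label(1, 0)), spacer),
            ]
        )
        allocs, _ = deconvolve(obs, sch, [spacer], min_reads=5)
        assert allocs[0].status == "absent"

    def test_unknown_barcode_triple_errors(self):
        sch = build_scheme(32)
        with pytest.raises(ConfigError):
            deconvolve({("XXXXXX", "Y", "Z"): Counter({"A": 1})}, sch, ["A" * 20])

    def test_depth_monotonicity(self):
        """Scaling read depth never moves a unique call to a different well."""
        sch = build_scheme(32)
        spacer = "ACGT" * 5
        for mult in (1, 10, 100):
            obs = dict(
                [
                    _observation_for(sch, PoolId(0, "position", "B3"), spacer, 10 * mult),
                    _observation_for(
                        sch, PoolId(0, "group", sch.group_label(1, 0)), spacer, 10 * mult
                    ),
                ]
            )
            allocs, _ = deconvolve(obs, sch, [spacer])
            assert allocs[0].status == "unique"
            assert allocs[0].address == WellAddress(0, 1, "B3")


class TestAllocationReport:
    def test_empty_observations_give_zero_coverage(self):
        sch = build_scheme(32)
        allocs, _ = deconvolve({}, sch, ["ACGT" * 5])
        rep = allocation_report(allocs, ["ACGT" * 5])
        assert rep["coverage"] == 0.0 and rep["n_absent"] == 1

    def test_noiseless_set_recovers_every_well(self, rng):
        """Deconvolution of a duplicate-free pooled set recovers each well exactly."""
        sch = build_scheme(2, plates_per_set=2)
        lib = [random_seq(rng, 20) for _ in range(2 * 96)]
        assert len(set(lib)) == len(lib)
        assign = simulate.arrange_in_plates([(f"m{i}", s) for i, s in enumerate(lib)], sch)
        reads, truth = simulate.simulate_pool_reads(assign, sch, depth=10, seed=3)
        obs, _ = demultiplex(reads, sch.barcodes)
        allocs, _ = deconvolve(obs, sch, lib)
        rep = allocation_report(allocs, lib)
        assert rep["coverage"] == 1.0
        by_spacer = {s: a for a, s in truth.items()}
        for a in allocs:
            assert a.status == "unique" and a.address == by_spacer[a.spacer]

    def test_duplicates_cause_ambiguity_never_false_uniques(self, rng):
        sch = build_scheme(2, plates_per_set=2)
        lib = [random_seq(rng, 20) for _ in range(150)]
        pool = [(f"m{i}", s) for i, s in enumerate(lib)]
        picked = simulate.simulate_picking(pool, 192, duplicate_bias=30.0, seed=11)
        assign = simulate.arrange_in_plates(picked, sch)
        reads, _ = simulate.simulate_pool_reads(assign, sch, depth=10, seed=4)
        obs, _ = demultiplex(reads, sch.barcodes)
        allocs, _ = deconvolve(obs, sch, lib)
        rep = allocation_report(allocs, lib)
        assert rep["n_ambiguous"] > 0
        wells_by_spacer = {}
        for addr, (_, s) in assign.items():
            wells_by_spacer.setdefault(s, set()).add(addr)
        false_calls = sum(
            1 for a in allocs
            if a.status == "unique" and a.address not in wells_by_spacer.get(a.spacer, set())
        )
        assert false_calls == 0
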