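"""Delta-array depth engine: accumulate/finalize/runs/AUC and their oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import covtally as ct
from covtally.coverage import (
    AlignmentInput,
    CoverageRun,
    DeltaArray,
    DepthConsistencyError,
    DepthVector,
    FilterConfig,
    accumulate,
    auc,
    depth_to_runs,
    finalize,
    passes_filters,
    tally_depth,
)
from covtally.simulate import brute_force_depth


def _mk(flags=0x0, mapq=30, pos=0, cigar="10M", chrom="c"):
    return AlignmentInput("r", flags, chrom, pos, mapq, cigar)


class TestFilters:
    def test_unmapped_always_fails(self):
        assert not passes_filters(_mk(flags=0x4), FilterConfig(exclude_flags=0), False)

    def test_mapq_zero_passes_all_pass(self):
        f = FilterConfig(exclude_flags=0x704)
        assert passes_filters(_mk(mapq=0), f, unique_pass=False)
        assert not passes_filters(_mk(mapq=0), f, unique_pass=True)

    def test_duplicate_excluded(self):
        assert not passes_filters(_mk(flags=0x400), FilterConfig(), False)

    def test_include_mask_required(self):
        f = FilterConfig(include_flags=0x2)
        assert not passes_filters(_mk(flags=0x0), f, False)
        assert passes_filters(_mk(flags=0x2), f, False)

    def test_bad_mask_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(exclude_flags=0x10000)


class TestAccumulateFinalize:
    def test_single_block_deltas(self):
        d = accumulate(DeltaArray("c", 20), [(0, 10)])
        assert d.deltas[0] == 1 and d.deltas[10] == -1
        assert d.deltas.sum() == 0

    def test_overlapping_blocks_prefix_sums(self):
        d = DeltaArray("c", 20)
        accumulate(d, [(0, 10)])
        accumulate(d, [(5, 15)])
        depth = finalize(d).depth
        expected = [1] * 5 + [2] * 5 + [1] * 5 + [0] * 5
        assert depth.tolist() == expected

    def test_end_decrement_at_chromosome_length(self):
        d = accumulate(DeltaArray("c", 10), [(5, 10)])
        assert finalize(d).depth.tolist() == [0] * 5 + [1] * 5

    def test_overhang_clamped_and_outside_skipped(self, caplog):
        d = DeltaArray("c", 10)
        with caplog.at_level("WARNING"):
            accumulate(d, [(8, 15), (20, 30)])
        assert finalize(d).depth.tolist() == [0] * 8 + [1] * 2
        assert "clamped" in caplog.text and "skipped" in caplog.text

    def test_zero_deltas_zero_depth(self):
        assert finalize(DeltaArray("c", 5)).depth.tolist() == [0] * 5

    def test_explicit_delta_spec(self):
        d = DeltaArray("c", 12)
        d.deltas[0] = 2
        d.deltas[5] = -1
        d.deltas[10] = -1
        assert finalize(d).depth.tolist() == [2] * 5 + [1] * 5 + [0] * 2

    def test_negative_prefix_sum_raises(self):
        d = DeltaArray("c", 5)
        d.deltas[2] = -1
        with pytest.raises(DepthConsistencyError):
            finalize(d)


@pytest.mark.parametrize("count_deletions", [True, False])
@pytest.mark.parametrize("unique_pass", [True, False])
def test_engine_equals_brute_force_random_reads(count_deletions, unique_pass):
    """1000 random synthetic reads: prefix-sum depth == per-base counting."""
    rng = np.random.default_rng(42)
    chroms = {"cA": 5_000, "cB": 3_000}
    recs = []
    for i in range(1000):
        chrom = "cA" if rng.random() < 0.6 else "cB"
        pos = int(rng.integers(0, chroms[chrom] - 400))
        kind = rng.random()
        if kind < 0.4:
            cigar = "100M"
        elif kind < 0.6:
            cigar = f"40M{int(rng.integers(30, 200))}N60M"
        elif kind < 0.8:
            cigar = f"50M{int(rng.integers(1, 5))}D50M"
        else:
            cigar = "5S90M5S"
        flags = 0x400 if rng.random() < 0.1 else 0x0
        mapq = int(rng.integers(0, 61))
        recs.append(AlignmentInput(f"r{i}", flags, chrom, pos, mapq, cigar))
    f = FilterConfig(count_deletions=count_deletions)
    engine = tally_depth(recs, chroms, filters=f, unique_pass=unique_pass)
    oracle = brute_force_depth(
        recs, chroms, filters=f, unique_pass=unique_pass, count_deletions=count_deletions
    )
    for c in chroms:
        np.testing.assert_array_equal(engine[c].depth, oracle[c])


def test_order_independence():
    rng = np.random.default_rng(0)
    chroms = {"c": 2_000}
    recs = [
        AlignmentInput(f"r{i}", 0, "c", int(rng.integers(0, 1_900)), 30, "100M")
        for i in range(200)
    ]
    base = tally_depth(recs, chroms)
    shuffled = list(recs)
    rng.shuffle(shuffled)
    np.testing.assert_array_equal(base["c"].depth, tally_depth(shuffled, chroms)["c"].depth)


def test_unique_depth_bounded_by_all(fixture_records):
    chroms, recs = fixture_records
    d_all = tally_depth(recs, chroms)
    d_uni = tally_depth(recs, chroms, unique_pass=True)
    for c in chroms:
        assert np.all(d_uni[c].depth <= d_all[c].depth)


class TestDepthToRuns:
    def test_example_runs(self):
        d = DepthVector("c", np.array([1, 1, 2, 2, 0, 3]))
        runs = depth_to_runs(d)
        assert runs == [
            CoverageRun("c", 0, 2, 1),
            CoverageRun("c", 2, 4, 2),
            CoverageRun("c", 5, 6, 3),
        ]
        with_zero = depth_to_runs(d, emit_zero_runs=True)
        assert CoverageRun("c", 4, 5, 0) in with_zero
        assert len(with_zero) == 4

    def test_all_zero_suppressed(self):
        assert depth_to_runs(DepthVector("c", np.zeros(10, dtype=np.int64))) == []

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=200))
    def test_round_trip_identity(self, values):
        d = DepthVector("c", np.array(values, dtype=np.int64))
        runs = depth_to_runs(d, emit_zero_runs=False)
        rebuilt = np.zeros(len(values), dtype=np.int64)
        for r in runs:
            rebuilt[r.start : r.end] = r.value
        np.testing.assert_array_equal(rebuilt, d.depth)
        # consecutive runs have different values
        for a, b in zip(runs, runs[1:]):
            if a.end == b.start:
                assert a.value != b.value


class TestAuc:
    RUNS = [CoverageRun("c", 0, 5, 1), CoverageRun("c", 5, 10, 2)]

    def test_total_without_annotation(self):
        r = auc(self.RUNS)
        assert r.total_auc == 15 and r.annotated_auc == 0 and r.unannotated_auc == 15

    def test_annotated_split(self):
        r = auc(self.RUNS, [("c", 3, 7)])
        assert r.total_auc == 15
        assert r.annotated_auc == 2 * 1 + 2 * 2
        assert r.unannotated_auc == 9

    def test_overlapping_annotation_rejected(self):
        with pytest.raises(ValueError, match="disjoin"):
            auc(self.RUNS, [("c", 0, 5), ("c", 3, 8)])

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(0, 5, 1_000)
        runs = depth_to_runs(DepthVector("c", depth))
        cuts = sorted({0, 1_000, *map(int, rng.integers(1, 999, 30))})
        partition = [("c", a, b) for a, b in zip(cuts, cuts[1:])]
        r = auc(runs, partition)
        assert r.annotated_auc == r.total_auc == int(depth.sum())
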