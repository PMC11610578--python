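"""DRR calling: interval algebra, complement/gap subtraction, Venn partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drrkit import (
    AlignmentBlock,
    Config,
    GenomicInterval,
    IntervalSet,
    call_drrs,
    covered_intervals,
    shared_missing,
    summarize_drrs,
)


def block(ts, te, mapq=60, seq="t1", tlen=1_000_000):
    return AlignmentBlock(
        query_id="q", query_len=tlen, query_start=ts, query_end=te,
        strand="+", target_id=seq, target_len=tlen,
        target_start=ts, target_end=te, matches=te - ts, block_len=te - ts,
        mapq=mapq,
    )


class TestCoveredIntervals:
    def test_union_of_overlapping_blocks(self):
        cov = covered_intervals([block(10, 60), block(50, 100)])
        assert cov.runs == {"t1": [(10, 100)]}

    def test_independent_unions_per_sequence(self):
        cov = covered_intervals([block(0, 10, seq="t1"), block(5, 20, seq="t2")])
        assert cov.runs == {"t1": [(0, 10)], "t2": [(5, 20)]}

    def test_mapq_filter(self):
        cov = covered_intervals([block(0, 10, mapq=0)], min_mapq=20)
        assert cov.is_empty()

    def test_block_beyond_sequence_length_rejected(self):
        from drrkit import ValidationError

        with pytest.raises(ValidationError):
            covered_intervals([block(0, 100)], seq_lengths={"t1": 50})


class TestCallDrrs:
    LEN = {"t1": 100_000}

    def test_complement_single_gap_in_coverage(self):
        cov = IntervalSet({"t1": [(0, 30_000), (45_000, 100_000)]})
        (d,) = call_drrs(cov, self.LEN)
        assert (d.interval.start, d.interval.end, d.size) == (30_000, 45_000, 15_000)
        assert d.drr_id == "DRR_t1_30000"

    def test_gap_subtraction_splits_uncovered_run(self):
        cov = IntervalSet({"t1": [(0, 20_000)]})
        gaps = IntervalSet({"t1": [(50_000, 60_000)]})
        drrs = call_drrs(cov, self.LEN, gaps)
        assert [(d.interval.start, d.interval.end) for d in drrs] == [
            (20_000, 50_000),
            (60_000, 100_000),
        ]
        assert sum(d.size for d in drrs) == 70_000

    @pytest.mark.parametrize(
        "size,expected", [(10_000, 0), (10_001, 1)], ids=["at-threshold", "just-above"]
    )
    def test_strictly_greater_than_threshold(self, size, expected):
        cov = IntervalSet({"t1": [(0, 50_000), (50_000 + size, 100_000)]})
        assert len(call_drrs(cov, self.LEN)) == expected

    def test_self_comparison_yields_zero(self):
        cov = IntervalSet({"t1": [(0, 100_000)]})
        drrs = call_drrs(cov, self.LEN)
        assert drrs == []
        assert summarize_drrs(drrs).total_bp == 0

    def test_order_invariance_of_blocks(self):
        blocks = [block(0, 30_000, tlen=100_000), block(45_000, 100_000, tlen=100_000)]
        a = call_drrs(covered_intervals(blocks), self.LEN)
        b = call_drrs(covered_intervals(blocks[::-1]), self.LEN)
        assert a == b

    def test_monotonicity_in_min_size(self):
        rng = np.random.default_rng(0)
        cov = IntervalSet.from_intervals(
            GenomicInterval("t1", s, s + int(rng.integers(1_000, 30_000)))
            for s in rng.integers(0, 70_000, size=8)
        )
        prev_n, prev_bp = None, None
        for min_size in [0, 5_000, 10_000, 20_000, 50_000]:
            drrs = call_drrs(cov, self.LEN, cfg=Config(min_drr_size=min_size))
            n, bp = len(drrs), sum(d.size for d in drrs)
            if prev_n is not None:
                assert n <= prev_n and bp <= prev_bp
            prev_n, prev_bp = n, bp

    def test_conservation_of_bases(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            cov_iv = [
                (int(s), int(s) + int(rng.integers(100, 20_000)))
                for s in rng.integers(0, 80_000, size=6)
            ]
            cov = IntervalSet({"t1": []}).union(
                IntervalSet.from_intervals(
                    GenomicInterval("t1", s, min(e, 100_000)) for s, e in cov_iv
                )
            )
            gap_s = int(rng.integers(0, 95_000))
            gaps = IntervalSet({"t1": [(gap_s, gap_s + 3_000)]})
            cfg = Config(min_drr_size=10_000)
            drrs = call_drrs(cov, self.LEN, gaps, cfg)
            uncovered = cov.complement(self.LEN)
            candidate = uncovered.subtract(gaps)
            sub_bp = sum(
                iv.size for iv in candidate.intervals() if iv.size <= cfg.min_drr_size
            )
            gap_uncovered_bp = gaps.subtract(cov).total_bp()
            total = (
                cov.total_bp()
                + sum(d.size for d in drrs)
                + gap_uncovered_bp
                + sub_bp
            )
            assert total == self.LEN["t1"]

    @settings(max_examples=60, deadline=None)
    @given(
        cov=st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 200)), max_size=8
        ),
        gaps=st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 200)), max_size=3
        ),
        min_size=st.integers(0, 300),
    )
    def test_matches_per_base_oracle(self, cov, gaps, min_size):
        """Exact equality with a per-base boolean-array scan on a 1 kbp toy."""
        length = 1_000
        cov_set = IntervalSet.from_intervals(
            GenomicInterval("t", s, min(s + l, length)) for s, l in cov
        )
        gap_set = IntervalSet.from_intervals(
            GenomicInterval("t", s, min(s + l, length)) for s, l in gaps
        )
        drrs = call_drrs(
            cov_set, {"t": length}, gap_set, Config(min_drr_size=min_size)
        )
        # oracle: mark covered and gap bases, scan maximal free runs
        mask = np.zeros(length, dtype=bool)
        for s, e in cov_set.runs.get("t", []):
            mask[s:e] = True
        for s, e in gap_set.runs.get("t", []):
            mask[s:e] = True
        expected = []
        run_start = None
        for i in range(length + 1):
            free = i < length and not mask[i]
            if free and run_start is None:
                run_start = i
            elif not free and run_start is not None:
                if i - run_start > min_size:
                    expected.append((run_start, i))
                run_start = None
        got = [(d.interval.start, d.interval.end) for d in drrs]
        # drop oracle runs that are pure gap-splits landing inside gaps: the
        # oracle marks gaps as unavailable, same as the caller, so sets match
        assert got == expected


class TestSummarize:
    @pytest.mark.parametrize(
        "sizes,n,total,median",
        [
            ([15_000], 1, 15_000, 15_000),
            ([10_001, 20_000, 30_000], 3, 60_001, 20_000),
            ([10_001, 20_000, 30_000, 40_000], 4, 100_001, 20_000),
        ],
        ids=["single", "odd", "even-lower-central"],
    )
    def test_order_statistics(self, sizes, n, total, median):
        from drrkit import DRRecord

        drrs = [
            DRRecord(f"d{i}", GenomicInterval("t", i * 100_000, i * 100_000 + s), "T", "Q")
            for i, s in enumerate(sizes)
        ]
        s = summarize_drrs(drrs)
        assert (s.n_regions, s.total_bp, s.median_bp) == (n, total, median)

    def test_empty_flagged_undefined(self):
        s = summarize_drrs([])
        assert (s.n_regions, s.total_bp) == (0, 0)
        assert s.min_bp is None and s.median_bp is None and s.max_bp is None


class TestSharedMissing:
    def test_two_query_partitions(self):
        q1 = IntervalSet({"t": [(0, 20_000)]})
        q2 = IntervalSet({"t": [(10_000, 30_000)]})
        inter, parts = shared_missing({"Q1": q1, "Q2": q2})
        assert inter.runs == {"t": [(10_000, 20_000)]}
        assert parts == {
            frozenset({"Q1"}): 10_000,
            frozenset({"Q2"}): 10_000,
            frozenset({"Q1", "Q2"}): 10_000,
        }

    def test_identical_sets(self):
        q = IntervalSet({"t": [(5, 50)]})
        inter, parts = shared_missing({"A": q, "B": q})
        assert inter.runs == q.runs
        assert parts == {frozenset({"A", "B"}): 45}

    def test_disjoint_sets(self):
        inter, parts = shared_missing(
            {"A": IntervalSet({"t": [(0, 10)]}), "B": IntervalSet({"t": [(20, 30)]})}
        )
        assert inter.is_empty()
        assert frozenset({"A", "B"}) not in parts

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            shared_missing({"A": IntervalSet({"t": [(0, 10)]})})

    def test_three_way_against_per_base_bitmask_oracle(self):
        rng = np.random.default_rng(3)
        length = 1_000
        sets = {}
        masks = {}
        for name in ["Q1", "Q2", "Q3"]:
            ivs = [
                (int(s), int(min(s + rng.integers(10, 200), length)))
                for s in rng.integers(0, 950, size=5)
            ]
            sets[name] = IntervalSet.from_intervals(
                GenomicInterval("t", s, e) for s, e in ivs
            )
            m = np.zeros(length, dtype=bool)
            for s, e in sets[name].runs["t"]:
                m[s:e] = True
            masks[name] = m
        inter, parts = shared_missing(sets)
        # oracle: per-base membership bitmask
        oracle = {}
        for i in range(length):
            members = frozenset(n for n in sets if masks[n][i])
            if members:
                oracle[members] = oracle.get(members, 0) + 1
        assert parts == oracle
        union_bp = int(np.any(list(masks.values()), axis=0).sum())
        assert sum(parts.values()) == union_bp
        assert inter.total_bp() == int(
            np.all(list(masks.values()), axis=0).sum()
        )
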