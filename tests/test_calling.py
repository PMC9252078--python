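"""The enhancer caller: counting, binomial scoring, FDR, merging, consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from starrkit.calling import (
    CallThresholds,
    EnhancerCall,
    FragmentLibrary,
    bh_fdr,
    call_enhancers,
    compute_window_stats,
    consensus_and_union,
    count_midpoints,
    dedup_fragments,
    replicate_concordance,
    window_stats,
)
from starrkit.intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    reciprocal_overlap,
)


def binom_upper_tail_oracle(c: int, n: int, p: float) -> float:
    """Independent brute-force P(X >= c): direct log-space term summation."""
    if c <= 0:
        return 1.0
    if p == 0:
        return 0.0
    total = 0.0
    for k in range(c, n + 1):
        logterm = (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * math.log(p) + (n - k) * math.log1p(-p)
        )
        total += math.exp(logterm)
    return min(total, 1.0)


def bh_oracle(p):
    """Brute-force BH step-up: q_i = min over p_(j) >= p_i of n p_(j) / rank(j)."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda k: p[k])
    q = [0.0] * n
    running = math.inf
    for rank in range(n, 0, -1):
        k = order[rank - 1]
        running = min(running, n * p[k] / rank)
        q[k] = min(running, 1.0)
    return q


class TestDedup:
    def test_exact_duplicates_collapsed(self):
        raw = IntervalSet(
            [GenomicInterval("chr1", 0, 600, "+")] * 3 + [GenomicInterval("chr1", 50, 650, "+")]
        )
        lib = dedup_fragments(raw)
        assert lib.total_unique == 2

    def test_strand_is_part_of_the_key(self):
        raw = IntervalSet(
            [GenomicInterval("chr1", 0, 600, "+"), GenomicInterval("chr1", 0, 600, "-")]
        )
        assert dedup_fragments(raw).total_unique == 2

    def test_empty(self):
        assert dedup_fragments(IntervalSet()).total_unique == 0


class TestCountMidpoints:
    ASM = GenomeAssembly(("chr1",), (3000,))

    def _lib(self, *frags):
        iset = IntervalSet([GenomicInterval(*f) for f in frags])
        return FragmentLibrary(iset, len(iset), "input")

    def test_midpoint_binning(self):
        counts = count_midpoints(self._lib(("chr1", 0, 600)), self.ASM, 600)
        assert list(counts) == [1, 0, 0, 0, 0]

    def test_boundary_midpoint_belongs_to_right_bin(self):
        counts = count_midpoints(self._lib(("chr1", 300, 900)), self.ASM, 600)
        assert list(counts) == [0, 1, 0, 0, 0]  # midpoint 600

    def test_conservation(self, small_study):
        lib = small_study.libraries[("PK15", "rep1", "cdna")]
        counts = count_midpoints(lib, small_study.genome.assembly, 600)
        assert counts.sum() == lib.total_unique

    def test_midpoint_outside_genome_is_error(self):
        asm = GenomeAssembly(("chr1",), (500,))
        with pytest.raises(ValueError, match="midpoint outside"):
            count_midpoints(self._lib(("chr1", 400, 700)), asm, 600)


class TestWindowStats:
    def test_zero_cdna(self):
        strength, p = window_stats(0, 5, 100, 100)
        assert strength == 0.0 and p == 1.0

    def test_balanced_window_frozen_value(self):
        # P(Bin(100, 0.05) >= 5) computed with the brute-force oracle
        strength, p = window_stats(5, 5, 100, 100)
        assert strength == pytest.approx(1.0)
        assert p == pytest.approx(0.5640, abs=5e-5)
        assert p == pytest.approx(binom_upper_tail_oracle(5, 100, 0.05), rel=1e-10)

    def test_enriched_window(self):
        strength, p = window_stats(10, 2, 1000, 1000)
        assert strength == pytest.approx(5.0)
        assert p == pytest.approx(binom_upper_tail_oracle(10, 1000, 0.002), rel=1e-10)

    def test_pseudo_count_on_zero_input(self):
        strength, p = window_stats(10, 0, 1000, 1000, pseudo=1)
        assert strength == pytest.approx(10.0)
        assert p == pytest.approx(binom_upper_tail_oracle(10, 1000, 0.001), rel=1e-10)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            window_stats(1, 1, 0, 100)

    @given(
        c=st.integers(0, 50),
        i=st.integers(0, 50),
        n=st.integers(100, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, c, i, n):
        _, p = window_stats(c, i, n, n)
        expected = binom_upper_tail_oracle(c, n, max(i, 1) / n)
        assert p == pytest.approx(expected, rel=1e-10, abs=1e-300)

    def test_p_monotone_in_cdna_count(self):
        ps = [window_stats(c, 5, 1000, 1000)[1] for c in range(0, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_with_monotone_enforcement(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_matches_brute_force_step_up(self, n):
        rng = np.random.default_rng(n)
        p = rng.random(n)
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


def _stats_df(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cdna_count", "input_count",
                 "strength", "p_value", "q_value"],
    )


class TestCallEnhancers:
    def test_nothing_passes(self):
        df = _stats_df([("chr1", 0, 600, 1, 1, 1.0, 0.5, 0.9)])
        assert call_enhancers(df) == []

    def test_abutting_windows_merge(self):
        df = _stats_df([
            ("chr1", 0, 600, 30, 5, 6.0, 1e-9, 1e-6),
            ("chr1", 600, 1200, 25, 5, 5.0, 1e-8, 1e-5),
        ])
        calls = call_enhancers(df)
        assert len(calls) == 1
        c = calls[0]
        assert (c.interval.start, c.interval.end) == (0, 1200)
        assert c.strength == 6.0 and c.best_p == 1e-9 and c.best_q == 1e-6

    def test_strength_exactly_one_excluded(self):
        df = _stats_df([("chr1", 0, 600, 10, 10, 1.0, 1e-9, 1e-6)])
        assert call_enhancers(df) == []

    def test_separated_windows_stay_separate(self):
        df = _stats_df([
            ("chr1", 0, 600, 30, 5, 6.0, 1e-9, 1e-6),
            ("chr1", 1200, 1800, 25, 5, 5.0, 1e-8, 1e-5),
        ])
        assert len(call_enhancers(df)) == 2


class TestReplicateConcordance:
    def _stats(self, strengths, counts=5):
        n = len(strengths)
        return _stats_df([
            ("chr1", 600 * k, 600 * (k + 1), counts, counts, s, 0.5, 1.0)
            for k, s in enumerate(strengths)
        ])

    def test_identical_vectors(self):
        a = self._stats([1.0, 2.0, 3.0, 4.0])
        assert replicate_concordance(a, a) == pytest.approx(1.0)

    def test_linear_pair_on_linear_scale(self):
        a = self._stats([1.0, 2.0, 3.0, 4.0])
        b = self._stats([2.0, 4.0, 6.0, 8.0])
        assert replicate_concordance(a, b, log_scale=False) == pytest.approx(1.0)

    def test_perfect_negative(self):
        a = self._stats([1.0, 2.0, 3.0, 4.0])
        b = self._stats([4.0, 3.0, 2.0, 1.0])
        assert replicate_concordance(a, b, log_scale=False) == pytest.approx(-1.0)

    def test_too_few_windows(self):
        a = self._stats([1.0])
        with pytest.raises(ValueError):
            replicate_concordance(a, a)

    def test_uninformative_windows_excluded(self):
        a = self._stats([1.0, 2.0, 3.0])
        b = self._stats([1.0, 2.0, 3.0])
        for df in (a, b):
            df.loc[2, ["cdna_count", "input_count"]] = 0
        # correlation computed over the two informative windows only
        assert replicate_concordance(a, b) == pytest.approx(1.0)


def _call(chrom, start, end, strength=2.0):
    return EnhancerCall(GenomicInterval(chrom, start, end), strength, 1e-6, 1e-4)


def consensus_oracle(calls_a, calls_b, min_frac=0.5):
    """Brute-force pairwise reciprocal-overlap check."""
    return sorted(
        (min(a.interval.start, b.interval.start), max(a.interval.end, b.interval.end))
        for a in calls_a
        for b in calls_b
        if reciprocal_overlap(a.interval, b.interval, min_frac)
    )


class TestConsensusAndUnion:
    def test_disjoint_sets(self):
        a = [_call("chr1", 0, 600)]
        b = [_call("chr1", 5000, 5600)]
        res = consensus_and_union({("PK15", "rep1"): a, ("ST", "rep1"): b})
        assert res.shared == []
        assert len(res.union) == 2

    def test_identical_sets(self):
        a = [_call("chr1", 0, 600)]
        res = consensus_and_union({("PK15", "rep1"): a, ("ST", "rep1"): list(a)})
        assert len(res.shared) == 1
        assert len(res.union) == 1

    def test_asymmetric_overlap_shared_and_union_span(self):
        a = [_call("chr1", 0, 1000)]
        b = [_call("chr1", 200, 800)]
        res = consensus_and_union({("PK15", "rep1"): a, ("ST", "rep1"): b})
        assert len(res.shared) == 1
        assert (res.shared[0].interval.start, res.shared[0].interval.end) == (0, 1000)
        assert len(res.union) == 1
        assert (res.union[0].interval.start, res.union[0].interval.end) == (0, 1000)

    def test_replicate_consensus_within_cell_line(self):
        r1 = [_call("chr1", 0, 600), _call("chr1", 10_000, 10_600)]
        r2 = [_call("chr1", 0, 600)]
        res = consensus_and_union({("PK15", "rep1"): r1, ("PK15", "rep2"): r2})
        assert len(res.consensus_by_cell["PK15"]) == 1

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [_call("chr1", s, s + int(l))
                 for s, l in zip(rng.integers(0, 50_000, 15), rng.integers(300, 2000, 15))]
            b = [_call("chr1", s, s + int(l))
                 for s, l in zip(rng.integers(0, 50_000, 15), rng.integers(300, 2000, 15))]
            res = consensus_and_union({("PK15", "rep1"): a, ("ST", "rep1"): b})
            got = sorted((c.interval.start, c.interval.end) for c in res.shared)
            assert got == sorted(set(consensus_oracle(a, b)))


class TestPipelineStats:
    def test_tested_windows_and_q_defaults(self, small_study):
        g = small_study.genome
        cdna = small_study.libraries[("PK15", "rep1", "cdna")]
        inp = small_study.libraries[("PK15", "rep1", "input")]
        stats = compute_window_stats(cdna, inp, g.assembly)
        empty = (stats["cdna_count"] + stats["input_count"]) == 0
        assert (stats.loc[empty, "q_value"] == 1.0).all()
        assert stats["cdna_count"].sum() == cdna.total_unique

    def test_sliding_windows_cover_planted_signal(self, small_study):
        g = small_study.genome
        cdna = small_study.libraries[("PK15", "rep1", "cdna")]
        inp = small_study.libraries[("PK15", "rep1", "input")]
        thr = CallThresholds(window_step=100)
        stats = compute_window_stats(cdna, inp, g.assembly, thr)
        calls = call_enhancers(stats, thr)
        recovered = sum(
            any(reciprocal_overlap(t.interval, c.interval, 0.5) for c in calls)
            for t in g.truth
        )
        assert recovered >= 0.9 * len(g.truth)
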