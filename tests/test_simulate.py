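"""The synthetic study generator: determinism, planted structure, calibration."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from starrkit.calling import count_midpoints
from starrkit.intervals import GenomicInterval, bin_genome
from starrkit.simulate import (
    SimConfig,
    simulate_expression,
    simulate_fragments,
    simulate_genome,
    simulate_hic,
    simulate_tracks,
)


def _frag_fingerprint(lib):
    f = lib.fragments
    return (tuple(f.chroms), tuple(f.starts), tuple(f.ends), tuple(f.strands))


class TestSimulateGenome:
    def test_deterministic_given_seed(self, small_config):
        g1 = simulate_genome(small_config)
        g2 = simulate_genome(small_config)
        assert tuple(g1.repeats.starts) == tuple(g2.repeats.starts)
        assert [t.interval for t in g1.truth] == [t.interval for t in g2.truth]
        assert [(x.gene_id, x.span) for x in g1.genes] == [(x.gene_id, x.span) for x in g2.genes]

    def test_zero_repeat_fraction(self, small_config):
        g = simulate_genome(replace(small_config, repeat_fraction=0.0,
                                    enhancer_repeat_fraction=0.0))
        assert len(g.repeats) == 0

    def test_repeat_fraction_hit_within_tolerance(self, small_genome, small_config):
        frac = small_genome.repeats.covered_bp() / small_genome.assembly.total_bp
        assert abs(frac - small_config.repeat_fraction) <= 0.02

    def test_enhancer_count_and_length(self, small_genome, small_config):
        assert len(small_genome.truth) == small_config.n_enhancers
        assert all(t.interval.length == small_config.enhancer_length
                   for t in small_genome.truth)
        assert all(t.activity >= 1 for t in small_genome.truth)

    def test_enhancer_repeat_mixing(self, small_genome, small_config):
        from starrkit.intervals import IntervalSet

        truth_set = IntervalSet([t.interval for t in small_genome.truth])
        in_repeat = truth_set.overlap_bp_with(small_genome.repeats) >= 300
        expected = round(small_config.enhancer_repeat_fraction * small_config.n_enhancers)
        assert int(in_repeat.sum()) == expected

    def test_infeasible_packing_rejected(self, small_config):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(replace(small_config, repeat_fraction=0.95))

    def test_genes_do_not_overlap(self, small_genome):
        by_chrom = {}
        for g in small_genome.genes:
            by_chrom.setdefault(g.span.chrom, []).append((g.span.start, g.span.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(repeat_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(activity_range=(0.5, 2.0))


class TestSimulateFragments:
    def test_deterministic_and_conserving(self, small_genome, small_config):
        a = simulate_fragments(small_genome, small_genome.truth, "input", 5000, 3)
        b = simulate_fragments(small_genome, small_genome.truth, "input", 5000, 3)
        assert _frag_fingerprint(a) == _frag_fingerprint(b)
        assert a.total_unique == 5000

    def test_lengths_clipped(self, small_genome):
        lib = simulate_fragments(small_genome, small_genome.truth, "input", 5000, 3)
        lens = lib.fragments.ends - lib.fragments.starts
        assert lens.min() >= 200 and lens.max() <= 1200

    def test_empty_library(self, small_genome):
        lib = simulate_fragments(small_genome, small_genome.truth, "input", 0, 3)
        assert lib.total_unique == 0

    def test_cdna_requires_pool(self, small_genome):
        with pytest.raises(ValueError, match="pool"):
            simulate_fragments(small_genome, small_genome.truth, "cdna", 100, 3)

    def test_cdna_resamples_pool_fragments(self, small_genome):
        inp = simulate_fragments(small_genome, small_genome.truth, "input", 2000, 3)
        cdna = simulate_fragments(small_genome, small_genome.truth, "cdna", 2000, 3,
                                  pool=inp)
        pool_coords = set(zip(inp.fragments.chroms, inp.fragments.starts,
                              inp.fragments.ends))
        cdna_coords = set(zip(cdna.fragments.chroms, cdna.fragments.starts,
                              cdna.fragments.ends))
        assert cdna_coords <= pool_coords

    def test_planted_enrichment_matches_closed_form(self):
        """One enhancer of activity 4 spanning 600 bp of a 1 Mb genome: the
        expected cDNA/input midpoint-count ratio in its window is
        4 / (1 + 3 * 600 / 1e6) ~= 3.99 under weighted pool resampling."""
        cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, n_genes=10,
                        n_enhancers=1, activity_range=(4.0, 4.0),
                        n_input_frags=1_000_000, n_cdna_frags=1_000_000, seed=11)
        g = simulate_genome(cfg)
        inp = simulate_fragments(g, g.truth, "input", cfg.n_input_frags, cfg.seed)
        cdna = simulate_fragments(g, g.truth, "cdna", cfg.n_cdna_frags, cfg.seed,
                                  pool=inp)
        t = g.truth[0].interval
        width = 600
        bin_idx = t.start // width
        ci = count_midpoints(inp, g.assembly, width)[bin_idx]
        cc = count_midpoints(cdna, g.assembly, width)[bin_idx]
        expected = 4 / (1 + 3 * 600 / 1e6)
        # Monte-Carlo tolerance: ratio sd ~ ratio * sqrt(1/ci + 1/cc)
        tol = 4 * expected * np.sqrt(1 / ci + 1 / cc)
        assert abs(cc / ci - expected) < tol

    def test_null_positional_uniformity(self, small_genome):
        """Under activity 1 everywhere the input library is positionally
        uniform: a chi-square over 600 bp tiles (expected proportional to
        tile length) should not reject at alpha = 0.01 in >= 95% of seeds."""
        tiles = bin_genome(small_genome.assembly, 600)
        widths = (tiles.ends - tiles.starts).astype(float)
        n = 20_000
        rejections = 0
        seeds = range(100, 120)
        for seed in seeds:
            lib = simulate_fragments(small_genome, [], "input", n, seed)
            counts = count_midpoints(lib, small_genome.assembly, 600)
            expected = n * widths / widths.sum()
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            p = stats.chi2.sf(chi2, len(widths) - 1)
            rejections += p < 0.01
        assert rejections <= 1  # >= 95% of 20 seeds


class TestSimulateTracks:
    def test_null_truth_no_peaks(self, small_genome):
        peaks, track = simulate_tracks(small_genome, [], "H3K27ac", 5,
                                       n_background_peaks=0)
        assert len(peaks) == 0
        assert all(np.all(v >= 0) for v in track.values.values())

    def test_seeded_reproducibility(self, small_genome):
        p1, t1 = simulate_tracks(small_genome, small_genome.truth, "ATAC", 5)
        p2, t2 = simulate_tracks(small_genome, small_genome.truth, "ATAC", 5)
        assert tuple(p1.starts) == tuple(p2.starts)
        for chrom in t1.values:
            assert np.array_equal(t1.values[chrom], t2.values[chrom])

    def test_planted_mark_yields_overlapping_peak(self, small_genome):
        peaks, _ = simulate_tracks(small_genome, small_genome.truth, "H3K9me3", 5,
                                   n_background_peaks=0)
        from starrkit.intervals import IntervalSet

        flagged = [t.interval for t in small_genome.truth if t.marks["H3K9me3"]]
        if flagged:
            truth_set = IntervalSet(flagged)
            assert truth_set.overlaps_any(peaks).all()

    def test_planted_signal_enriched_over_input(self, small_genome):
        peaks, chip = simulate_tracks(small_genome, small_genome.truth, "H3K9me3", 5,
                                      n_background_peaks=0)
        _, inp = simulate_tracks(small_genome, small_genome.truth, "INPUT", 5)
        from starrkit.chromatin import fold_enrichment

        for pk in peaks:
            assert fold_enrichment(chip, inp, pk, pseudo=0.1) >= 2.0

    def test_unknown_mark_rejected(self, small_genome):
        with pytest.raises(ValueError, match="unknown mark"):
            simulate_tracks(small_genome, small_genome.truth, "H3K36me3", 5)


class TestSimulateHic:
    def test_symmetric_matrices(self, small_genome):
        hic = simulate_hic(small_genome, [], resolution=40_000, seed=5)
        for m in hic.matrices.values():
            assert np.array_equal(m.matrix, m.matrix.T)

    def test_tads_partition_without_overlap(self, small_genome):
        hic = simulate_hic(small_genome, [], resolution=40_000, seed=5)
        tads = hic.tads
        for chrom in set(tads.chroms):
            sel = tads.chroms == chrom
            s, e = tads.starts[sel], tads.ends[sel]
            assert np.all(s[1:] >= e[:-1])

    def test_null_distance_ratio_near_one(self, small_genome):
        """Without boosts, observed diagonal means track the power-law
        expectation C/(1+d) within Poisson error."""
        hic = simulate_hic(small_genome, [], resolution=40_000, seed=5,
                           tad_boost=1.0, base_contacts=100.0)
        m = next(iter(hic.matrices.values()))
        n = m.n_bins
        for d in range(0, min(10, n)):
            lam = 100.0 / (1 + d)
            diag = np.diagonal(m.matrix, offset=d)
            se = np.sqrt(lam / diag.size)
            assert abs(diag.mean() - lam) < 5 * se

    def test_linked_pair_ratio_matches_boost(self, small_genome):
        """Monte-Carlo mean of observed/expected at the boosted pair ~= beta."""
        iv = GenomicInterval("chr1", 40_800, 41_400)
        tss = 240_000  # 5 bins away
        ratios = []
        for seed in range(100):
            hic = simulate_hic(small_genome, [(iv, tss)], resolution=40_000,
                               seed=seed, tad_boost=1.0, link_boost=5.0)
            m = hic.matrices["chr1"]
            bi, bj = iv.midpoint // 40_000, tss // 40_000
            lam = 100.0 / (1 + abs(bi - bj))
            ratios.append(m.matrix[bi, bj] / lam)
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.1)

    def test_resolution_must_give_two_bins(self, small_genome):
        with pytest.raises(ValueError, match="< 2 bins"):
            simulate_hic(small_genome, [], resolution=10_000_000, seed=5)


class TestSimulateExpression:
    def test_all_silent(self, small_genome):
        fpkm = simulate_expression(small_genome.genes, 5, silent_fraction=1.0)
        assert all(v == 0.0 for v in fpkm.values())

    def test_none_silent(self, small_genome):
        fpkm = simulate_expression(small_genome.genes, 5, silent_fraction=0.0)
        assert all(v > 0.0 for v in fpkm.values())

    def test_seeded_reproducibility(self, small_genome):
        a = simulate_expression(small_genome.genes, 5)
        b = simulate_expression(small_genome.genes, 5)
        assert a == b


class TestStudyBundle:
    def test_all_components_present(self, small_study, small_config):
        assert len(small_study.genome.truth) == small_config.n_enhancers
        assert set(small_study.tracks) == {
            "ATAC", "H3K4me1", "H3K4me3", "H3K27ac", "H3K9me3", "H3K27me3", "CTCF"
        }
        assert len(small_study.expression) == small_config.n_genes
        assert len(small_study.qtls) > 0
        assert set(small_study.hic.matrices) == {"chr1", "chr2"}

    def test_oversized_qtls_present_for_filter_exercise(self, small_study):
        lengths = {c: l for c, l in zip(small_study.genome.assembly.chrom_names,
                                        small_study.genome.assembly.chrom_lengths)}
        oversized = [q for q in small_study.qtls
                     if q.interval.length > 0.5 * lengths[q.interval.chrom]]
        assert len(oversized) > 0
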