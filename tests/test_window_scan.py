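"""Window grid, thresholds, Fisher enrichment, sweep calling/merging."""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovisweep as ov
from ovisweep.window_scan import (ScanThresholds, SweepRegion,
                                  annotate_sweeps, assign_windows,
                                  call_sweeps, empirical_threshold,
                                  fine_map_region, fisher_window_enrichment,
                                  flag_windows, merge_sweeps, shared_genes)


class TestAssignWindows:
    def test_boundary_convention(self):
        W = 50_000
        wins = assign_windows(np.array(["1", "1"], dtype=object),
                              np.array([50_000, 50_001]),
                              {"1": 120_000}, W)
        by_site = {}
        for w in wins:
            for j in w.site_idx:
                by_site[j] = w.index
        assert by_site[0] == 0 and by_site[1] == 1

    def test_reported_grid_matches_scan_table_style(self):
        """A site at 90,623,456 reports window 90,600,001-90,650,000."""
        wins = assign_windows(np.array(["chr7"], dtype=object),
                              np.array([90_623_456]),
                              {"chr7": 100_000_000}, 50_000)
        (w,) = [w for w in wins if w.site_idx]
        assert (w.start1, w.end1) == (90_600_001, 90_650_000)

    def test_partition_property(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), size=300,
                                 replace=False))
        wins = assign_windows(np.array(["1"] * 300, dtype=object), pos,
                              {"1": 1_000_000}, 50_000)
        all_sites = sorted(j for w in wins for j in w.site_idx)
        assert all_sites == list(range(300))

    def test_site_beyond_length_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            assign_windows(np.array(["1"], dtype=object),
                           np.array([2_000_001]), {"1": 2_000_000})

    def test_last_window_short(self):
        wins = assign_windows(np.array([], dtype=object),
                              np.array([], dtype=np.int64),
                              {"1": 120_000}, 50_000)
        assert [(w.start, w.end) for w in wins] == \
            [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]


class TestEmpiricalThreshold:
    def test_integer_quantile(self):
        vals = np.arange(1, 101, dtype=float)
        cut = empirical_threshold(vals, 0.05)
        assert cut == 96
        assert sorted(vals[vals >= cut]) == [96, 97, 98, 99, 100]

    def test_all_ties_all_outliers(self):
        vals = np.full(50, 3.14)
        cut = empirical_threshold(vals, 0.05)
        assert (vals >= cut).all()

    def test_outlier_count_bound(self, rng):
        vals = rng.integers(0, 500, size=10_000).astype(float)
        f = 0.05
        cut = empirical_threshold(vals, f)
        n_out = (vals >= cut).sum()
        n_ties = (vals == cut).sum()
        assert f * 10_000 <= n_out <= f * 10_000 + n_ties

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            empirical_threshold(np.arange(10.0), 0.05)


class TestFisher:
    def test_k_zero_is_one(self):
        assert fisher_window_enrichment(0, 10, 100, 1000) == 1.0

    def test_all_significant_window(self):
        p = fisher_window_enrichment(8, 8, 16, 200)
        oracle = Fraction(sum(comb(16, i) * comb(184, 8 - i)
                              for i in range(8, 9)), comb(200, 8))
        assert p == pytest.approx(float(oracle), rel=1e-9)
        assert p < 0.05

    def test_exact_tail_example(self):
        p = fisher_window_enrichment(8, 10, 100, 1000)
        oracle = Fraction(sum(comb(100, i) * comb(900, 10 - i)
                              for i in range(8, 11)), comb(1000, 10))
        assert p == pytest.approx(float(oracle), abs=1e-12)

    def test_matches_rational_oracle_random(self, rng):
        for _ in range(100):
            M = int(rng.integers(20, 400))
            K = int(rng.integers(1, M))
            m = int(rng.integers(1, min(M, 30)))
            k = int(rng.integers(0, min(m, K) + 1))
            p = fisher_window_enrichment(k, m, K, M)
            oracle = Fraction(
                sum(comb(K, i) * comb(M - K, m - i)
                    for i in range(k, min(m, K) + 1)), comb(M, m))
            assert p == pytest.approx(float(oracle), abs=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_enrichment(5, 4, 100, 1000)


def _toy_table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({
        "chrom": "1", "window": np.arange(n),
        "start1": np.arange(n) * 50_000 + 1,
        "end1": (np.arange(n) + 1) * 50_000,
        "n_snps": 20,
        "weighted_fst": rng.uniform(0, 0.2, n),
        "max_abs_xpehh": rng.uniform(0, 2, n),
        "fisher_p": rng.uniform(0.2, 1.0, n),
        "pi_sel": 1.0, "pi_ref": 1.0, "pi_ratio": 1.0,
        "tajd_sel": 0.0, "tajd_ref": 0.0, "n_sig_snps": 0,
    })
    return t


class TestCallSweeps:
    def test_two_planted_outliers(self):
        t = _toy_table()
        for w in (30, 70):
            t.loc[w, ["weighted_fst", "max_abs_xpehh", "fisher_p"]] = \
                [0.9, 5.0, 1e-6]
        sweeps = call_sweeps(t)
        assert [(s.start, s.end) for s in sweeps] == \
            [(30 * 50_000, 31 * 50_000), (70 * 50_000, 71 * 50_000)]

    def test_fst_only_not_called_under_intersect(self):
        t = _toy_table()
        t.loc[30, ["weighted_fst", "fisher_p"]] = [0.9, 1e-6]
        assert call_sweeps(t) == []

    def test_loosening_to_full_tail_flags_all(self):
        t = _toy_table()
        th = ScanThresholds(fst_tail=1.0, xpehh_tail=1.0,
                            fisher_alpha=1.0)
        flagged = flag_windows(t, th)
        # every unmasked window passes both (near-)full tails
        assert flagged["fst_outlier"].all()
        assert flagged["xpehh_outlier"].all()

    def test_monotone_in_thresholds(self):
        t = _toy_table(seed=3)
        t.loc[10, ["weighted_fst", "max_abs_xpehh", "fisher_p"]] = \
            [0.9, 5.0, 1e-6]
        tight = flag_windows(t, ScanThresholds(fst_tail=0.05,
                                               xpehh_tail=0.05))
        loose = flag_windows(t, ScanThresholds(fst_tail=0.2,
                                               xpehh_tail=0.2))
        assert (loose["sweep_flag"] | ~tight["sweep_flag"]).all()

    def test_xpehh_1pct_rule(self):
        t = _toy_table(seed=4)
        t.loc[55, "max_abs_xpehh"] = 9.0
        sweeps = call_sweeps(t, rule="xpehh_1pct")
        assert any(s.start <= 55 * 50_000 < s.end for s in sweeps)


class TestMergeSweeps:
    def mk(self, chrom, start, end):
        return SweepRegion(chrom=chrom, start=start, end=end,
                           windows=[start // 50_000])

    def test_gap_below_threshold_merges(self):
        merged = merge_sweeps([self.mk("1", 100_000, 150_000),
                               self.mk("1", 180_000, 230_000)], 50_000)
        assert [(m.start, m.end) for m in merged] == [(100_000, 230_000)]

    def test_gap_exactly_50kb_merges(self):
        merged = merge_sweeps([self.mk("1", 100_000, 150_000),
                               self.mk("1", 200_000, 250_000)], 50_000)
        assert len(merged) == 1

    def test_gap_above_threshold_not_merged(self):
        merged = merge_sweeps([self.mk("1", 100_000, 150_000),
                               self.mk("1", 200_001, 250_000)], 50_000)
        assert len(merged) == 2

    def test_different_chromosomes_never_merge(self):
        merged = merge_sweeps([self.mk("1", 0, 50_000),
                               self.mk("2", 0, 50_000)], 50_000)
        assert len(merged) == 2

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6)),
                    min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    def test_idempotent_and_order_independent(self, spans, rnd):
        regions = [self.mk("1", a * 50_000, (a + w) * 50_000)
                   for a, w in spans]
        once = merge_sweeps(regions)
        assert [(m.start, m.end) for m in merge_sweeps(once)] == \
            [(m.start, m.end) for m in once]
        shuffled = list(regions)
        rnd.shuffle(shuffled)
        assert [(m.start, m.end) for m in merge_sweeps(shuffled)] == \
            [(m.start, m.end) for m in once]
        # merged sweeps pairwise separated by more than the gap
        for a, b in zip(once, once[1:]):
            assert b.start - a.end > 50_000


class TestAnnotateSweeps:
    def test_overlap_attached(self):
        sw = [SweepRegion("1", 100_000, 230_000)]
        genes = [ov.GeneAnnotation("G1", "1", 120_000, 130_000)]
        assert annotate_sweeps(sw, genes)[0].genes == ["G1"]

    def test_halfopen_abutment_not_attached(self):
        sw = [SweepRegion("1", 100_000, 230_000)]
        genes = [ov.GeneAnnotation("G0", "1", 90_000, 100_000),
                 ov.GeneAnnotation("G2", "1", 230_000, 240_000)]
        assert annotate_sweeps(sw, genes)[0].genes == []

    def test_matches_quadratic_overlap_oracle(self, rng):
        sweeps = [SweepRegion("1", int(a), int(a) + int(w))
                  for a, w in zip(rng.integers(0, 10**6, 20),
                                  rng.integers(1, 10**5, 20))]
        genes = [ov.GeneAnnotation(f"g{k}", "1", int(a), int(a) + int(w))
                 for k, (a, w) in enumerate(zip(
                     rng.integers(0, 10**6, 50),
                     rng.integers(1, 10**5, 50)))]
        out = annotate_sweeps(sweeps, genes)
        for sw in out:
            want = sorted(g.name for g in genes
                          if max(g.start, sw.start) < min(g.end, sw.end))
            assert sw.genes == want


class TestSharedGenes:
    def test_triple_intersection(self):
        out = shared_genes({"a": {"A", "B", "C"}, "b": {"B", "C", "D"},
                            "c": {"C"}})
        assert out["all"] == ["C"]
        assert out[("a", "b")] == ["B", "C"]

    def test_disjoint_empty(self):
        assert shared_genes({"a": {"A"}, "b": {"B"}})["all"] == []

    def test_matches_nested_loop_oracle(self, rng):
        sets = {name: set(rng.choice(200, size=100, replace=False).tolist())
                for name in ("x", "y", "z")}
        out = shared_genes(sets)
        brute = sorted(g for g in sets["x"]
                       if g in sets["y"] and g in sets["z"])
        assert out["all"] == brute


class TestFineMap:
    def _pair(self, rng):
        from conftest import random_haplotypes

        h = random_haplotypes(rng, 40, 60, spacing=800)
        h_sel = ov.HaplotypeMatrix(sites=h.sites, samples=h.samples[:10],
                                   haplotypes=h.haplotypes[:20])
        h_ref = ov.HaplotypeMatrix(sites=h.sites, samples=h.samples[10:],
                                   haplotypes=h.haplotypes[20:])
        return h_sel, h_ref

    def test_single_subwindow_consistent_with_genome_row(self, rng):
        h_sel, h_ref = self._pair(rng)
        xp = ov.xpehh_scan(h_sel, h_ref)
        region = fine_map_region(h_sel, h_ref, "1", 0, 48_000,
                                 sub_window=48_000, xpehh=xp)
        assert len(region) == 1
        row = region.iloc[0]
        zw = xp["z"].to_numpy()
        want = np.nanmax(np.abs(zw)) if np.isfinite(zw).any() else np.nan
        if math.isnan(want):
            assert math.isnan(row.max_abs_xpehh)
        else:
            assert row.max_abs_xpehh == pytest.approx(want)
        d = ov.tajimas_d(h_sel.haplotypes)
        assert row.tajd_sel == pytest.approx(d.tajima_d)

    def test_overlapping_steps_tile_region(self, rng):
        h_sel, h_ref = self._pair(rng)
        xp = ov.xpehh_scan(h_sel, h_ref)
        region = fine_map_region(h_sel, h_ref, "1", 0, 48_000,
                                 sub_window=10_000, step=5_000, xpehh=xp)
        starts = region["start1"].to_numpy() - 1
        ends = region["end1"].to_numpy()
        assert starts[0] == 0 and ends[-1] == 48_000
        # union of spans covers the region
        covered = np.zeros(48_000, dtype=bool)
        for s, e in zip(starts, ends):
            covered[s:e] = True
        assert covered.all()
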