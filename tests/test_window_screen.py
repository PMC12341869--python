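import math

import numpy as np
import pytest

from sdscreen.errors import ConfigError
from sdscreen.io_formats import Locus
from sdscreen.popgen_stats import LocusStats
from sdscreen.window_screen import (
    CandidateRegion,
    ScreenConfig,
    call_candidates,
    classify_system,
    sliding_windows,
)


def make_stats(fst_values, fis_values, positions=None, chroms=None):
    n = len(fst_values)
    if positions is None:
        positions = [100 * (j + 1) for j in range(n)]
    if chroms is None:
        chroms = ["chr1"] * n
    loci = [Locus(c, int(p), "A", "C", 60.0) for c, p in zip(chroms, positions)]
    stats = [
        LocusStats(
            index=j, p_m=0.5, p_f=0.0, n_m=5, n_f=5, ho_m=1.0, ho_f=0.0,
            a=0.0, b=0.0, c=0.0, fst=fst_values[j], fis=fis_values[j], maf=0.25,
        )
        for j in range(n)
    ]
    return stats, loci


class TestScreenConfig:
    def test_defaults(self):
        cfg = ScreenConfig()
        assert (cfg.window_k, cfg.fst_min, cfg.fis_max, cfg.min_span_bp) == (
            10, 0.3, -0.5, 1000
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_k": 1},
            {"shift": 2},
            {"fst_min": 0.0},
            {"fst_min": 1.5},
            {"fis_max": 0.1},
            {"min_span_bp": -5},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            ScreenConfig(**kwargs)


class TestSlidingWindows:
    def test_window_count(self):
        stats, loci = make_stats([0.1] * 12, [0.0] * 12)
        wins = sliding_windows(stats, loci, ScreenConfig(window_k=10))
        assert len(wins) == 3  # 12 - 10 + 1

    def test_short_chromosome_no_windows(self):
        stats, loci = make_stats([0.1] * 5, [0.0] * 5)
        assert sliding_windows(stats, loci, ScreenConfig(window_k=10)) == []

    def test_constant_mean(self):
        stats, loci = make_stats([0.4] * 10, [-0.6] * 10)
        (w,) = sliding_windows(stats, loci, ScreenConfig(window_k=10))
        assert w.mean_fst == pytest.approx(0.4)
        assert w.mean_fis == pytest.approx(-0.6)
        assert w.start_pos == 100 and w.end_pos == 1000

    def test_windows_never_span_chromosomes(self):
        chroms = ["chr1"] * 6 + ["chr2"] * 6
        positions = [100 * (j + 1) for j in range(6)] * 2
        stats, loci = make_stats([0.1] * 12, [0.0] * 12,
                                 positions=positions, chroms=chroms)
        wins = sliding_windows(stats, loci, ScreenConfig(window_k=5))
        assert len(wins) == 4  # 2 per chromosome
        assert all(len({loci[i].chrom for i in w.snp_indices}) == 1 for w in wins)

    def test_nan_excluded_from_means(self):
        fst = [0.4, float("nan"), 0.2, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4]
        fis = [-0.6] * 10
        stats, loci = make_stats(fst, fis)
        (w,) = sliding_windows(stats, loci, ScreenConfig(window_k=10))
        expected = np.mean([v for v in fst if not math.isnan(v)])
        assert w.mean_fst == pytest.approx(expected)
        assert w.n_defined == 9
        assert not w.low_confidence

    def test_mostly_nan_flagged_low_confidence(self):
        fst = [float("nan")] * 6 + [0.4] * 4
        stats, loci = make_stats(fst, [-0.6] * 10)
        (w,) = sliding_windows(stats, loci, ScreenConfig(window_k=10))
        assert w.low_confidence

    def test_window_means_match_direct_recomputation(self, rng):
        fst = rng.uniform(-0.2, 0.8, size=60)
        fis = rng.uniform(-1, 0.5, size=60)
        fst[rng.random(60) < 0.2] = np.nan
        stats, loci = make_stats(list(fst), list(fis))
        for w in sliding_windows(stats, loci, ScreenConfig(window_k=7)):
            sl = fst[w.snp_indices]
            assert w.mean_fst == pytest.approx(np.nanmean(sl), nan_ok=True)


class TestCallCandidates:
    def test_single_passing_window(self):
        stats, loci = make_stats(
            [0.35] * 10, [-0.6] * 10, positions=range(1000, 3001, 222)
        )
        cfg = ScreenConfig(window_k=10)
        wins = sliding_windows(stats, loci, cfg)
        (region,) = call_candidates(wins, stats, cfg)
        assert region.passes_span  # span 2777 - 1000 + 1 > 1000
        assert region.mean_fst == pytest.approx(0.35)

    def test_fst_below_threshold_no_region(self):
        stats, loci = make_stats([0.25] * 10, [-0.9] * 10)
        cfg = ScreenConfig(window_k=10)
        regions = call_candidates(sliding_windows(stats, loci, cfg), stats, cfg)
        assert regions == []

    def test_span_exactly_1kb_fails_strict_rule(self):
        # 10 SNPs spanning exactly 1000 bp inclusive
        positions = np.linspace(5000, 5999, 10).astype(int)
        stats, loci = make_stats([0.4] * 10, [-0.8] * 10, positions=positions)
        cfg = ScreenConfig(window_k=10)
        (region,) = call_candidates(sliding_windows(stats, loci, cfg), stats, cfg)
        assert region.span_bp == 1000
        assert not region.passes_span

    def test_overlapping_windows_merge(self):
        stats, loci = make_stats([0.4] * 14, [-0.8] * 14)
        cfg = ScreenConfig(window_k=10)
        wins = sliding_windows(stats, loci, cfg)
        assert len(wins) == 5
        (region,) = call_candidates(wins, stats, cfg)
        assert region.snp_indices == list(range(14))

    def test_separate_signals_stay_separate(self):
        fst = [0.5] * 10 + [0.0] * 15 + [0.5] * 10
        fis = [-1.0] * 10 + [0.0] * 15 + [-1.0] * 10
        stats, loci = make_stats(fst, fis)
        cfg = ScreenConfig(window_k=10)
        regions = call_candidates(sliding_windows(stats, loci, cfg), stats, cfg)
        assert len(regions) == 2

    def test_emitted_regions_satisfy_thresholds(self, rng):
        fst = rng.uniform(-0.2, 0.8, size=300)
        fis = rng.uniform(-1, 0.3, size=300)
        stats, loci = make_stats(list(fst), list(fis))
        cfg = ScreenConfig(window_k=10)
        wins = sliding_windows(stats, loci, cfg)
        for region in call_candidates(wins, stats, cfg):
            member = [w for w in wins
                      if set(w.snp_indices) <= set(region.snp_indices)
                      and w.mean_fst >= cfg.fst_min and w.mean_fis <= cfg.fis_max]
            assert member, "region without any passing window"

    def test_monotone_in_thresholds(self, rng):
        fst = rng.uniform(-0.2, 0.8, size=200)
        fis = rng.uniform(-1, 0.3, size=200)
        stats, loci = make_stats(list(fst), list(fis))

        def snps_called(fst_min, fis_max):
            cfg = ScreenConfig(window_k=5, fst_min=fst_min, fis_max=fis_max)
            wins = sliding_windows(stats, loci, cfg)
            return {
                i for r in call_candidates(wins, stats, cfg) for i in r.snp_indices
            }

        base = snps_called(0.3, -0.5)
        assert snps_called(0.4, -0.5) <= base
        assert snps_called(0.3, -0.6) <= base

    def test_chromosome_order_invariance(self, rng):
        fst = list(rng.uniform(-0.2, 0.8, size=60))
        fis = list(rng.uniform(-1, 0.3, size=60))
        pos = [100 * (j + 1) for j in range(30)] * 2
        cfg = ScreenConfig(window_k=5)

        def run(a_first: bool):
            # same per-chromosome data, opposite processing order
            f_a, f_b = fst[:30], fst[30:]
            i_a, i_b = fis[:30], fis[30:]
            if a_first:
                stats, loci = make_stats(
                    f_a + f_b, i_a + i_b, pos, ["chrA"] * 30 + ["chrB"] * 30
                )
            else:
                stats, loci = make_stats(
                    f_b + f_a, i_b + i_a, pos, ["chrB"] * 30 + ["chrA"] * 30
                )
            wins = sliding_windows(stats, loci, cfg)
            return {
                (r.chrom, r.start_pos, r.end_pos, round(r.mean_fst, 12))
                for r in call_candidates(wins, stats, cfg)
            }

        assert run(True) == run(False)


class TestClassifySystem:
    def _region(self, n=5):
        return CandidateRegion("chr1", 100, 500, 401, list(range(n)))

    def test_xy(self):
        r = self._region()
        assert classify_system(r, np.ones(5), np.zeros(5)) == "XY"

    def test_zw(self):
        r = self._region()
        assert classify_system(r, np.zeros(5), np.ones(5)) == "ZW"

    def test_ambiguous_when_equal(self):
        r = self._region()
        assert classify_system(r, np.full(5, 0.5), np.full(5, 0.5)) == "ambiguous"

    def test_margin_respected(self):
        r = self._region()
        assert classify_system(r, np.full(5, 0.6), np.full(5, 0.5)) == "ambiguous"
        assert (
            classify_system(r, np.full(5, 0.6), np.full(5, 0.5), margin=0.05)
            == "XY"
        )
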