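"""Composite landscape analyses: size effects, profiles, contrasts."""

import numpy as np
import pandas as pd
import pytest

from recland.features import FeatureSet
from recland.landscape import (LandscapeError, category_rate_contrast,
                               distance_profile, micro_macro_contrast,
                               profile_flank_trend, rt_overlap_contrast,
                               size_rate_correlation)
from recland.ratemap import RateMap, chromosome_summary


def fs(rows):
    return FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "category", "id"]))


def const_map(chrom, L, r):
    return RateMap(chrom, [0], [L], [r])


def summaries_from(rates_by_len):
    out = []
    for i, (L, r) in enumerate(rates_by_len):
        out.append(chromosome_summary(const_map(f"chr{i}", L, r), L))
    return out


class TestSizeRate:
    def test_strictly_decreasing_gives_minus_one(self):
        s = summaries_from([(40_000_000, 1e-8), (20_000_000, 2e-8),
                            (10_000_000, 3e-8), (5_000_000, 4e-8)])
        r = size_rate_correlation(s)
        assert r.tau == pytest.approx(-1.0)

    def test_constant_rates_flagged(self):
        s = summaries_from([(40_000_000, 1e-8), (20_000_000, 1e-8),
                            (10_000_000, 1e-8)])
        assert size_rate_correlation(s).zero_variance

    def test_too_few_chromosomes(self):
        s = summaries_from([(40_000_000, 1e-8), (20_000_000, 2e-8)])
        with pytest.raises(LandscapeError):
            size_rate_correlation(s)


class TestMicroMacro:
    def test_ratio_and_welch(self):
        s = summaries_from([(40_000_000, 1e-8), (30_000_000, 1.1e-8),
                            (25_000_000, 0.9e-8),
                            (10_000_000, 3e-8), (5_000_000, 3.2e-8),
                            (2_000_000, 2.8e-8)])
        out = micro_macro_contrast(s)
        assert out["ratio"] == pytest.approx(3.0, rel=0.1)
        assert out["p_value"] < 0.05

    def test_empty_class_named(self):
        s = summaries_from([(40_000_000, 1e-8), (30_000_000, 1e-8)])
        with pytest.raises(LandscapeError, match="micro"):
            micro_macro_contrast(s)

    def test_single_member_class_rejected(self):
        s = summaries_from([(40_000_000, 1e-8), (30_000_000, 1e-8),
                            (5_000_000, 3e-8)])
        with pytest.raises(LandscapeError):
            micro_macro_contrast(s)


class TestDistanceProfile:
    def test_constant_map_flat_profile(self):
        maps = {"chr1": const_map("chr1", 2_000_000, 1e-8)}
        anchors = fs([("chr1", p, p + 1, "+", "TSS", str(p))
                      for p in (500_000, 900_000, 1_200_000)])
        prof = distance_profile(maps, anchors, bin_size=5000, span=200_000)
        np.testing.assert_allclose(prof.mean_rate, 1.0)
        assert prof.offsets.size == 80

    def test_planted_downstream_peak(self):
        """10x rate in [anchor, anchor+5 kb) puts the maximum in the first
        downstream bin."""
        anchors_pos = [300_000, 600_000, 900_000]
        maps = {}
        starts, ends, rates = [], [], []
        prev = 0
        for p in anchors_pos:
            starts += [prev, p]
            ends += [p, p + 5000]
            rates += [1e-8, 1e-7]
            prev = p + 5000
        starts.append(prev)
        ends.append(1_500_000)
        rates.append(1e-8)
        maps["chr1"] = RateMap("chr1", starts, ends, rates)
        anchors = fs([("chr1", p, p + 1, "+", "TSS", str(p))
                      for p in anchors_pos])
        prof = distance_profile(maps, anchors)
        peak_bin = np.nanargmax(prof.mean_rate)
        assert prof.offsets[peak_bin] == 0
        assert prof.mean_rate[peak_bin] == pytest.approx(10.0)

    def test_strand_symmetry(self, rng):
        """Minus-strand anchors give the same profile as mirrored
        plus-strand anchors."""
        L = 1_000_000
        n = 40
        cuts = np.sort(rng.choice(np.arange(1, L // 1000), 199, replace=False)) * 1000
        bounds = np.concatenate([[0], cuts, [L]])
        rates = rng.uniform(1e-9, 5e-8, bounds.size - 1)
        fwd = RateMap("chr1", bounds[:-1], bounds[1:], rates)
        # mirrored map on a second chromosome
        rev = RateMap("chr2", L - bounds[1:][::-1], L - bounds[:-1][::-1],
                      rates[::-1])
        pos = rng.integers(250_000, L - 250_000, n)
        plus = fs([("chr1", int(p), int(p) + 1, "+", "TSS", str(i))
                   for i, p in enumerate(pos)])
        minus = fs([("chr2", L - 1 - int(p), L - int(p), "-", "TSS", str(i))
                    for i, p in enumerate(pos)])
        prof_plus = distance_profile({"chr1": fwd}, plus)
        prof_minus = distance_profile({"chr2": rev}, minus)
        np.testing.assert_allclose(prof_plus.mean_rate, prof_minus.mean_rate,
                                   rtol=1e-9)

    def test_translation_invariance(self):
        maps = {"c": RateMap("c", [0, 10_000], [10_000, 400_000],
                             [5e-8, 1e-8])}
        anchors = fs([("c", 210_000, 210_001, "+", "TSS", "a")])
        prof1 = distance_profile(maps, anchors)
        shift = 50_000
        maps2 = {"c": RateMap("c", [shift, 10_000 + shift],
                              [10_000 + shift, 400_000 + shift], [5e-8, 1e-8])}
        anchors2 = fs([("c", 210_000 + shift, 210_001 + shift, "+", "TSS", "a")])
        prof2 = distance_profile(maps2, anchors2)
        np.testing.assert_allclose(prof1.mean_rate, prof2.mean_rate)

    def test_no_anchors_rejected(self):
        with pytest.raises(LandscapeError):
            distance_profile({"c": const_map("c", 1000, 1e-8)}, fs([]))


class TestFlankTrend:
    def make_profile(self, shape):
        maps = {"c": const_map("c", 2_000_000, 1e-8)}
        anchors = fs([("c", 1_000_000, 1_000_001, "+", "TSS", "a")])
        prof = distance_profile(maps, anchors)
        prof.mean_rate = shape(prof.centers)
        return prof

    def test_symmetric_peak_signs(self):
        prof = self.make_profile(lambda c: 10 - np.abs(c) / 50_000)
        up, down = profile_flank_trend(prof)
        assert up.tau > 0 and down.tau < 0

    def test_flat_profile_flagged(self):
        prof = self.make_profile(lambda c: np.ones_like(c))
        up, down = profile_flank_trend(prof)
        assert up.zero_variance and down.zero_variance


class TestCategoryContrast:
    def test_shifted_category_significant(self, rng):
        windows = rng.exponential(5.0, 2000)
        cats = {"CpGi": windows[:200] * 10.0, "gene": rng.permutation(windows)[:300]}
        out = category_rate_contrast(cats, windows)
        row = out[out["category"] == "CpGi"].iloc[0]
        assert row["p_adjusted"] < 0.001
        assert row["median"] > np.median(windows)

    def test_null_category_not_significant_mostly(self, rng):
        # same-distribution category: adjusted p behaves like a null draw
        pvals = []
        for _ in range(20):
            windows = rng.exponential(5.0, 1000)
            cats = {"cat": rng.permutation(windows)[:150]}
            out = category_rate_contrast(cats, windows)
            pvals.append(out["p_value"].iloc[0])
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.25
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_member_flagged_low_n(self, rng):
        out = category_rate_contrast({"one": [5.0]}, rng.exponential(5, 100))
        assert bool(out["low_n"].iloc[0])

    def test_input_order_invariance(self, rng):
        windows = rng.exponential(5.0, 500)
        vals = rng.exponential(9.0, 80)
        p1 = category_rate_contrast({"c": vals}, windows)["p_value"].iloc[0]
        p2 = category_rate_contrast({"c": rng.permutation(vals)},
                                    windows)["p_value"].iloc[0]
        assert p1 == pytest.approx(p2)


class TestRTOverlapContrast:
    def test_planted_boost_detected(self, rng):
        """Features overlapping LINEs have doubled rates -> significant."""
        L = 2_000_000
        n = 200
        cell = 1000
        starts = np.arange(0, L, cell)
        rates = np.full(starts.size, 1e-8) * rng.lognormal(0, 0.3, starts.size)
        feat_starts = rng.choice(np.arange(100, L - 3000, 5000), n, replace=False)
        line_rows = []
        for i, s in enumerate(np.sort(feat_starts)[:n // 2]):
            line_rows.append(("c", int(s), int(s) + 2000, "+", "LINE", f"L{i}"))
            rates[s // cell: s // cell + 2] *= 2.0
        maps = {"c": RateMap("c", starts, starts + cell, rates)}
        feats = fs([("c", int(s), int(s) + 2000, "+", "gene", str(i))
                    for i, s in enumerate(np.sort(feat_starts))])
        out = rt_overlap_contrast(maps, {"gene": feats}, fs(line_rows))
        row = out[(out["category"] == "gene") & (out["family"] == "LINE")].iloc[0]
        assert row["p_value"] < 0.01
        assert row["mean_with"] > row["mean_without"]

    def test_empty_family_cells_missing(self, rng):
        maps = {"c": const_map("c", 100_000, 1e-8)}
        feats = fs([("c", 0, 1000, "+", "gene", "g")])
        out = rt_overlap_contrast(maps, {"gene": feats}, fs([]))
        assert out["p_value"].isna().all()
        assert (out["n_with"] == 0).all()


class TestPlotting:
    def test_profile_and_landscape_figures_render(self, tmp_path, rng):
        import matplotlib
        matplotlib.use("Agg")
        from recland.plotting import plot_landscape, plot_profile
        maps = {"c": const_map("c", 2_000_000, 1e-8)}
        anchors = fs([("c", 1_000_000, 1_000_001, "+", "TSS", "a")])
        prof = distance_profile(maps, anchors)
        plot_profile(prof, tmp_path / "p.png")
        w = maps["c"].window_rates(100_000)
        plot_landscape(w, path=tmp_path / "l.png")
        assert (tmp_path / "p.png").stat().st_size > 0
        assert (tmp_path / "l.png").stat().st_size > 0


class TestInsideAnchorValue:
    def test_interval_anchors_report_own_span_mean(self):
        # islands sit on a 10x segment: inside-mean reflects it exactly
        starts = [0, 100_000, 102_000]
        ends = [100_000, 102_000, 500_000]
        maps = {"c": RateMap("c", starts, ends, [1e-8, 1e-7, 1e-8])}
        anchors = fs([("c", 100_000, 102_000, "+", "CpGi", "i")])
        prof = distance_profile(maps, anchors, orient_by_strand=False)
        assert prof.inside_mean == pytest.approx(10.0)
        assert prof.inside_n == 1
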