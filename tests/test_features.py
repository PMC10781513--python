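"""Feature geometry: ingestion, derivations, densities, overlap splits."""

import numpy as np
import pandas as pd
import pytest

from recland.features import (FeatureError, FeatureSet, derive_intergenic,
                              derive_promoters, derive_tss,
                              mean_rate_by_feature, overlap_split,
                              read_features, tile_windows,
                              window_density_coverage)
from recland.ratemap import RateMap

from conftest import per_base_rates, random_rate_map


def fs(rows):
    return FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "category", "id"]))


class TestIO:
    def test_gff3_one_based_normalised(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=t1\n")
        out = read_features(p)
        row = out.df.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (100, 200, "+")
        assert row["category"] == "mRNA" and row["id"] == "t1"

    def test_bed_halfopen_kept(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        row = read_features(p, category="CpGi").df.iloc[0]
        assert (row["start"], row["end"], row["category"]) == (100, 200, "CpGi")

    def test_bed_zero_length_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(FeatureError):
            read_features(p)

    def test_unknown_strand_warned_to_plus(self, caplog):
        s = fs([("chr1", 0, 10, ".", "gene", "g")])
        assert s.df["strand"].iloc[0] == "+"


class TestTSS:
    def test_plus_strand(self):
        tss = derive_tss(fs([("chr1", 100, 200, "+", "mRNA", "t")]))
        assert (tss.df["start"].iloc[0], tss.df["end"].iloc[0]) == (100, 101)

    def test_minus_strand_mirror(self):
        tss = derive_tss(fs([("chr1", 100, 200, "-", "mRNA", "t")]))
        assert (tss.df["start"].iloc[0], tss.df["end"].iloc[0]) == (199, 200)

    def test_shared_start_deduplicated(self):
        tss = derive_tss(fs([("chr1", 100, 200, "+", "mRNA", "a"),
                             ("chr1", 100, 300, "+", "mRNA", "b")]))
        assert len(tss) == 1


class TestPromoters:
    def test_upstream_window(self):
        tss = fs([("chr1", 5000, 5001, "+", "TSS", "t")])
        p = derive_promoters(tss).df.iloc[0]
        assert (p["start"], p["end"]) == (3000, 5000)

    def test_clip_at_chromosome_start(self):
        tss = fs([("chr1", 1000, 1001, "+", "TSS", "t")])
        p = derive_promoters(tss).df.iloc[0]
        assert (p["start"], p["end"]) == (0, 1000)

    def test_minus_strand_downstream_coordinates(self):
        tss = fs([("chr1", 5000, 5001, "-", "TSS", "t")])
        p = derive_promoters(tss).df.iloc[0]
        assert (p["start"], p["end"]) == (5001, 7001)

    def test_single_bp_cpgi_overlap_labels(self):
        tss = fs([("chr1", 5000, 5001, "+", "TSS", "t")])
        cpgi = fs([("chr1", 4999, 5002, "+", "CpGi", "i")])
        p = derive_promoters(tss, cpgi=cpgi).df.iloc[0]
        assert p["category"] == "promoter_with_CpGi"
        cpgi2 = fs([("chr1", 5000, 5100, "+", "CpGi", "i")])  # abuts only
        p2 = derive_promoters(tss, cpgi=cpgi2).df.iloc[0]
        assert p2["category"] == "promoter_without_CpGi"

    def test_strand_mirror_symmetry(self, rng):
        """Reflecting coordinates + strands maps promoters onto their
        reflections exactly."""
        L = 100_000
        starts = np.sort(rng.integers(3000, L - 3000, 20))
        tss_plus = fs([("chr1", int(s), int(s) + 1, "+", "TSS", str(i))
                       for i, s in enumerate(starts)])
        tss_minus = fs([("chr1", L - 1 - int(s), L - int(s), "-", "TSS", str(i))
                        for i, s in enumerate(starts)])
        p_plus = derive_promoters(tss_plus, chrom_lengths={"chr1": L})
        p_minus = derive_promoters(tss_minus, chrom_lengths={"chr1": L})
        refl = sorted((L - e, L - s) for s, e in
                      zip(p_minus.df["start"], p_minus.df["end"]))
        direct = sorted(zip(p_plus.df["start"], p_plus.df["end"]))
        assert refl == [tuple(map(int, d)) for d in direct]


class TestIntergenic:
    def test_union_complement(self):
        genes = fs([("chr1", 100, 200, "+", "gene", "a"),
                    ("chr1", 150, 300, "+", "gene", "b")])
        inter = derive_intergenic(genes, {"chr1": 400})
        got = list(zip(inter.df["start"], inter.df["end"]))
        assert got == [(0, 100), (300, 400)]

    def test_no_genes_whole_chromosome(self):
        inter = derive_intergenic(fs([]), {"chr1": 500})
        assert list(zip(inter.df["start"], inter.df["end"])) == [(0, 500)]

    def test_full_tiling_empty(self):
        genes = fs([("chr1", 0, 500, "+", "gene", "a")])
        assert len(derive_intergenic(genes, {"chr1": 500})) == 0

    def test_complement_roundtrip(self, rng):
        """Complementing the complement recovers the merged gene union."""
        rows = []
        pos = 0
        for i in range(10):
            s = pos + int(rng.integers(10, 100))
            e = s + int(rng.integers(10, 200))
            rows.append(("chr1", s, e, "+", "gene", str(i)))
            pos = e
        L = pos + 50
        genes = fs(rows)
        inter = derive_intergenic(genes, {"chr1": L})
        back = derive_intergenic(inter, {"chr1": L})
        merged = genes.merged_intervals("chr1")
        got = np.array(list(zip(back.df["start"], back.df["end"])))
        np.testing.assert_array_equal(got, merged)


class TestDensityCoverage:
    def test_single_feature(self, small_windows):
        f = fs([("chr1", 100, 200, "+", "x", "a")])
        d = window_density_coverage(f, small_windows, "density")
        c = window_density_coverage(f, small_windows, "coverage")
        assert list(d) == [1, 0, 0]
        assert c[0] == pytest.approx(0.1)

    def test_union_coverage_overlapping_features(self, small_windows):
        f = fs([("chr1", 100, 200, "+", "x", "a"),
                ("chr1", 150, 250, "+", "x", "b")])
        c = window_density_coverage(f, small_windows, "coverage")
        d = window_density_coverage(f, small_windows, "density")
        assert c[0] == pytest.approx(0.15)
        assert d[0] == 2

    def test_abutting_feature_counts_next_window_only(self, small_windows):
        f = fs([("chr1", 1000, 1100, "+", "x", "a")])
        d = window_density_coverage(f, small_windows, "density")
        assert list(d) == [0, 1, 0]

    def test_spanning_feature_counts_once_per_window(self, small_windows):
        f = fs([("chr1", 500, 2500, "+", "x", "a")])
        d = window_density_coverage(f, small_windows, "density")
        assert list(d) == [1, 1, 1]

    def test_matches_brute_force(self, rng):
        """Density and coverage equal per-base brute force on random input."""
        L = 10_000
        wsize = 1_000
        wins = tile_windows({"chr1": L}, wsize)
        rows = [("chr1", int(s), int(s) + int(rng.integers(1, 800)), "+", "x", str(i))
                for i, s in enumerate(rng.integers(0, L - 800, 40))]
        f = fs(rows)
        cov = window_density_coverage(f, wins, "coverage")
        dens = window_density_coverage(f, wins, "density")
        covered = np.zeros(L, dtype=bool)
        for _, s, e, *_ in rows:
            covered[s:e] = True
        for k in range(len(wins)):
            s, e = wins["start"][k], wins["end"][k]
            assert cov[k] == pytest.approx(covered[s:e].mean())
            want = sum(1 for _, fs_, fe_, *_ in rows if fs_ < e and fe_ > s)
            assert dens[k] == want

    def test_coverage_bounds_density_integer(self, rng):
        wins = tile_windows({"chr1": 10_000}, 1000)
        rows = [("chr1", int(s), int(s) + 100, "+", "x", str(i))
                for i, s in enumerate(rng.integers(0, 9_900, 30))]
        f = fs(rows)
        cov = window_density_coverage(f, wins, "coverage")
        dens = window_density_coverage(f, wins, "density")
        assert np.all((cov >= 0) & (cov <= 1))
        assert np.all(dens == dens.astype(int)) and np.all(dens >= 0)


class TestMeanRateByFeature:
    def test_constant_map_gives_constant(self):
        maps = {"chr1": RateMap("chr1", [0], [10_000], [1e-8])}
        f = fs([("chr1", 100, 200, "+", "gene", "a")])
        per_feature, per_cat = mean_rate_by_feature(maps, f)
        assert per_feature["rate"].iloc[0] == pytest.approx(1.0)
        assert per_cat["mean"].iloc[0] == pytest.approx(1.0)

    def test_feature_in_gap_excluded(self):
        maps = {"chr1": RateMap("chr1", [0], [100], [1e-8])}
        f = fs([("chr1", 200, 300, "+", "gene", "a"),
                ("chr1", 0, 50, "+", "gene", "b")])
        per_feature, per_cat = mean_rate_by_feature(maps, f)
        assert per_feature["rate"].isna().sum() == 1
        assert per_cat["n"].iloc[0] == 1

    def test_category_mean_matches_per_base_oracle(self, rng):
        m = random_rate_map(rng, span=10_000)
        maps = {"chr": m}
        arr = per_base_rates(m)
        rows, want = [], []
        for i in range(20):
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(50, 900))
            rows.append(("chr", s, e, "+", "cat", str(i)))
            seg = arr[s:e]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                want.append(seg.mean() * 1e8)
        f = fs(rows)
        _, per_cat = mean_rate_by_feature(maps, f)
        assert per_cat["mean"].iloc[0] == pytest.approx(np.mean(want), rel=1e-10)


class TestOverlapSplit:
    def test_basic_split(self):
        genes = fs([("chr1", 0, 100, "+", "gene", "a")])
        lines = fs([("chr1", 50, 60, "+", "LINE", "l")])
        w, wo = overlap_split(genes, lines, family="LINE")
        assert len(w) == 1 and len(wo) == 0

    def test_abutting_is_not_overlap(self):
        genes = fs([("chr1", 0, 100, "+", "gene", "a")])
        lines = fs([("chr1", 100, 110, "+", "LINE", "l")])
        w, wo = overlap_split(genes, lines, family="LINE")
        assert len(w) == 0 and len(wo) == 1

    def test_empty_rt_set_all_non_overlapping(self):
        genes = fs([("chr1", 0, 100, "+", "gene", "a")])
        w, wo = overlap_split(genes, fs([]))
        assert len(w) == 0 and len(wo) == 1

    def test_partition_exhaustive_disjoint(self, rng):
        rows = [("chr1", int(s), int(s) + 50, "+", "gene", str(i))
                for i, s in enumerate(rng.integers(0, 10_000, 50))]
        rts = [("chr1", int(s), int(s) + 30, "+", "LINE", f"L{i}")
               for i, s in enumerate(rng.integers(0, 10_000, 20))]
        w, wo = overlap_split(fs(rows), fs(rts))
        assert len(w) + len(wo) == 50
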