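"""Composite landscape analyses.

These operations tie the rate-map calculus, feature geometry and rank
statistics together into the study-level questions: does recombination
rise as chromosomes shrink; how much hotter are microchromosomes; how do
rates behave as a function of distance from TSS and CpG islands; do
annotation categories deviate from the genome-wide rate distribution; and
does retrotransposon presence inside a category shift its rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSet, mean_rate_by_feature, overlap_mask
from .ratemap import ChromosomeSummary
from .stats import (CorrelationResult, adjust, kendall_tau_b, welch_t,
                    wilcoxon_rank_sum)

logger = logging.getLogger(__name__)


class LandscapeError(ValueError):
    pass


# -------------------------------------------------------- chromosome level
def size_rate_correlation(summaries: list[ChromosomeSummary]) -> CorrelationResult:
    """Kendall tau between log10 chromosome length and mean rate (cM/Mb).

    The log transform cannot change tau (rank invariance); it is kept for
    parity with how chromosome size is conventionally reported.
    """
    if len(summaries) < 3:
        raise LandscapeError("need >= 3 chromosomes")
    sizes = np.log10([s.length_bp for s in summaries])
    rates = np.array([s.mean_rate_cM_Mb for s in summaries])
    return kendall_tau_b(sizes, rates)


def micro_macro_contrast(summaries: list[ChromosomeSummary]) -> dict:
    """Class means of cM/Mb rates and a Welch's t contrast micro vs macro."""
    micro = np.array([s.mean_rate_cM_Mb for s in summaries
                      if s.size_class == "micro"])
    macro = np.array([s.mean_rate_cM_Mb for s in summaries
                      if s.size_class == "macro"])
    for name, arr in (("micro", micro), ("macro", macro)):
        if arr.size == 0:
            raise LandscapeError(f"no {name} chromosomes in the summary set")
    if micro.size < 2 or macro.size < 2:
        raise LandscapeError("Welch's t needs >= 2 chromosomes per class")
    t, p = welch_t(micro, macro)
    return {
        "micro_mean": float(micro.mean()),
        "macro_mean": float(macro.mean()),
        "ratio": float(micro.mean() / macro.mean()),
        "t": t,
        "p_value": p,
        "n_micro": int(micro.size),
        "n_macro": int(macro.size),
    }


# --------------------------------------------------------------- profiles
@dataclass
class DistanceProfile:
    """Mean rate as a function of signed distance from a set of anchors.

    ``offsets`` are bin-start offsets (bp; negative = upstream in feature
    orientation), each bin spanning ``[offset, offset + bin_size)``.
    """

    offsets: np.ndarray
    mean_rate: np.ndarray          # cM/Mb
    n_anchors: np.ndarray
    ci_half_width: np.ndarray
    bin_size: int
    # mean rate over the anchors' own spans (meaningful for interval
    # anchors such as CpG islands; equals the 0-offset bin for 1-bp ones)
    inside_mean: float = float("nan")
    inside_n: int = 0

    @property
    def centers(self) -> np.ndarray:
        return self.offsets + self.bin_size / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets, "center": self.centers,
            "mean_rate_cM_Mb": self.mean_rate, "n": self.n_anchors,
            "ci95_half_width": self.ci_half_width,
        })


def distance_profile(maps: dict, anchors: FeatureSet, bin_size: int = 5_000,
                     span: int = 200_000,
                     orient_by_strand: bool = True) -> DistanceProfile:
    """Average rate in ``bin_size`` windows spanning ``span`` bp up- and
    downstream of each anchor's zero point.

    The zero point is the anchor's start (strand-aware first base when
    ``orient_by_strand``: for '-' anchors the offset axis is mirrored so
    that positive offsets still mean downstream of the feature).  Bins with
    no covered map interval for an anchor are excluded from that bin's mean.
    The 95% band is mean +/- 1.96 * SE across anchors.
    """
    df = anchors.df
    if not len(df):
        raise LandscapeError("no anchors")
    offsets = np.arange(-span, span, bin_size, dtype=np.int64)
    nbins = offsets.size
    sums = np.zeros(nbins)
    sq = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    inside_sum = 0.0
    inside_n = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        m = maps.get(chrom)
        if m is None:
            continue
        ivals, _ = m.region_means(sub["start"].to_numpy(),
                                  sub["end"].to_numpy())
        ivals = ivals[np.isfinite(ivals)] * 1e8
        inside_sum += ivals.sum()
        inside_n += ivals.size
        zero = sub["start"].to_numpy()
        minus = orient_by_strand & (sub["strand"].to_numpy() == "-")
        for k, off in enumerate(offsets):
            # genomic interval for this signed-offset bin, per anchor
            gs = np.where(minus, zero - (off + bin_size) + 1, zero + off)
            ge = gs + bin_size
            ok = gs >= 0
            if not ok.any():
                continue
            vals, _ = m.region_means(gs[ok], ge[ok])
            vals = vals[np.isfinite(vals)] * 1e8
            sums[k] += vals.sum()
            sq[k] += (vals ** 2).sum()
            counts[k] += vals.size
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq - counts * mean ** 2) / np.maximum(counts - 1, 1),
            np.nan,
        )
        ci = 1.96 * np.sqrt(np.maximum(var, 0) / np.maximum(counts, 1))
    return DistanceProfile(
        offsets, mean, counts, ci, bin_size,
        inside_mean=inside_sum / inside_n if inside_n else float("nan"),
        inside_n=inside_n,
    )


def profile_flank_trend(profile: DistanceProfile, flank: int = 50_000):
    """Kendall tau of (offset, mean rate) over the upstream [-flank, 0) and
    downstream (0, +flank] bins, tested separately."""
    centers = profile.centers
    up = (centers >= -flank) & (centers < 0) & np.isfinite(profile.mean_rate)
    down = (centers > 0) & (centers <= flank) & np.isfinite(profile.mean_rate)
    if not up.any() or not down.any():
        raise LandscapeError("profile does not cover the requested flank")
    return (kendall_tau_b(centers[up], profile.mean_rate[up]),
            kendall_tau_b(centers[down], profile.mean_rate[down]))


# -------------------------------------------------------------- contrasts
def category_rate_contrast(category_rates: dict, genome_window_rates,
                           method: str = "holm") -> pd.DataFrame:
    """Wilcoxon rank-sum of each category's per-feature rates against the
    genome-wide per-window rate distribution, with multiplicity adjustment
    across categories.

    ``category_rates`` maps category label -> array of per-feature mean
    rates (cM/Mb); ``genome_window_rates`` is the genome-wide windowed rate
    distribution on the same scale.
    """
    ref = np.asarray(genome_window_rates, dtype=float)
    ref = ref[np.isfinite(ref)]
    rows = []
    for cat, vals in category_rates.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("category %s empty; skipped", cat)
            continue
        u, p = wilcoxon_rank_sum(vals, ref)
        rows.append({
            "category": cat, "n": int(vals.size),
            "median": float(np.median(vals)), "mean": float(vals.mean()),
            "U": u, "p_value": p, "low_n": vals.size < 3,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = adjust(out["p_value"].to_numpy(), method)
    return out


def rt_overlap_contrast(maps: dict, features_by_category: dict,
                        rts: FeatureSet,
                        families=("LTR", "LINE", "SINE")) -> pd.DataFrame:
    """Rate contrast of features with vs without retrotransposon overlap.

    For every (annotation category, RT family) cell: mean/median per-feature
    rate of the overlapping and non-overlapping subsets and a Wilcoxon
    rank-sum p-value.  Empty cells are reported with NaN, not raised.
    """
    rows = []
    for cat, fs in features_by_category.items():
        per_feature, _ = mean_rate_by_feature(maps, fs)
        rate = per_feature["rate"].to_numpy()
        for fam in families:
            mask = overlap_mask(fs, rts, family=fam)
            vals_with = rate[mask & np.isfinite(rate)]
            vals_without = rate[~mask & np.isfinite(rate)]
            row = {
                "category": cat, "family": fam,
                "n_with": int(vals_with.size),
                "n_without": int(vals_without.size),
                "mean_with": float(vals_with.mean()) if vals_with.size else np.nan,
                "mean_without": float(vals_without.mean()) if vals_without.size else np.nan,
                "median_with": float(np.median(vals_with)) if vals_with.size else np.nan,
                "median_without": float(np.median(vals_without)) if vals_without.size else np.nan,
            }
            if vals_with.size and vals_without.size:
                _, p = wilcoxon_rank_sum(vals_with, vals_without)
                row["p_value"] = p
            else:
                row["p_value"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def correlate_window_columns(windows: pd.DataFrame, columns: list[str],
                             method: str = "holm") -> pd.DataFrame:
    """Pairwise Kendall tau-b over named window-table columns (long format)."""
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            res = kendall_tau_b(windows[a], windows[b])
            rows.append({"var1": a, "var2": b, "tau": res.tau,
                         "p_value": res.p_value, "n": res.n,
                         "zero_variance": res.zero_variance})
    out = pd.DataFrame(rows)
    if len(out):
        finite = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = adjust(out.loc[finite, "p_value"].to_numpy(),
                                            method)
        out["p_adjusted"] = adj
    return out
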