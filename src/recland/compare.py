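"""Cross-species / cross-population conservation of recombination maps.

Both maps must live on a shared reference coordinate system (the study
design maps both species' reads to one assembly, so no lift-over is
needed here).  Conservation is quantified as windowed Kendall tau-b,
genome-wide and per chromosome, plus a per-window normalized difference
``log10(rate_A) - log10(rate_B)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import CorrelationResult, kendall_tau_b

logger = logging.getLogger(__name__)


class CompareError(ValueError):
    pass


@dataclass
class MapComparison:
    window_size: int
    pairs: pd.DataFrame                       # chrom, start, end, rate_a, rate_b
    genome_wide: CorrelationResult | None = None
    per_chromosome: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)   # chrom -> reason


def align_windows(maps_a: dict, maps_b: dict, window_size: int,
                  chrom_lengths: dict | None = None,
                  min_covered_fraction: float = 0.5) -> pd.DataFrame:
    """Identical window tilings over both maps; keep windows defined in both.

    Chromosomes present in only one species are dropped with a log message;
    fully disjoint chromosome name sets raise.
    """
    shared = [c for c in maps_a if c in maps_b]
    if not shared:
        raise CompareError(
            f"no shared chromosomes: {sorted(maps_a)} vs {sorted(maps_b)}"
        )
    for c in set(maps_a) ^ set(maps_b):
        logger.info("chromosome %s present in only one map; skipped", c)
    frames = []
    for chrom in shared:
        L = (chrom_lengths or {}).get(
            chrom, max(maps_a[chrom].span, maps_b[chrom].span)
        )
        wa = maps_a[chrom].window_rates(window_size, min_covered_fraction, L)
        wb = maps_b[chrom].window_rates(window_size, min_covered_fraction, L)
        sub = wa[["chrom", "start", "end"]].copy()
        sub["rate_a"] = wa["rate_cM_Mb"]
        sub["rate_b"] = wb["rate_cM_Mb"]
        frames.append(sub.dropna(subset=["rate_a", "rate_b"]))
    return pd.concat(frames, ignore_index=True)


def conservation_stats(pairs: pd.DataFrame, per_chromosome: bool = True,
                       min_pairs: int = 3):
    """Kendall tau-b of paired window rates, genome-wide and per chromosome.

    Units (chromosomes) with fewer than ``min_pairs`` pairs are skipped with
    a recorded reason.  Returns ``(genome_wide, per_chrom, skipped)``.
    """
    skipped = {}
    if len(pairs) < min_pairs:
        raise CompareError(f"fewer than {min_pairs} paired windows overall")
    genome_wide = kendall_tau_b(pairs["rate_a"], pairs["rate_b"])
    per_chrom = {}
    if per_chromosome:
        for chrom, sub in pairs.groupby("chrom", sort=False):
            if len(sub) < min_pairs:
                skipped[chrom] = f"only {len(sub)} paired windows"
                continue
            per_chrom[chrom] = kendall_tau_b(sub["rate_a"], sub["rate_b"])
    return genome_wide, per_chrom, skipped


def normalized_log_difference(pairs: pd.DataFrame, base: float = 10.0):
    """Per-window ``log(rate_a) - log(rate_b)`` difference track.

    Windows where either rate is <= 0 are dropped (an epsilon pad would
    dominate the tails); the drop count is returned alongside.
    """
    ok = (pairs["rate_a"] > 0) & (pairs["rate_b"] > 0)
    dropped = int((~ok).sum())
    sub = pairs[ok].copy()
    logb = np.log(base)
    sub["log_diff"] = (np.log(sub["rate_a"]) - np.log(sub["rate_b"])) / logb
    return sub[["chrom", "start", "end", "log_diff"]], dropped


def snp_density_mask(densities_a: dict, densities_b: dict,
                     min_density: float) -> dict:
    """Chromosomes whose SNP density (variants/kb) falls below
    ``min_density`` in either species, with the reason recorded."""
    excluded = {}
    for chrom in set(densities_a) | set(densities_b):
        for label, dens in (("A", densities_a), ("B", densities_b)):
            d = dens.get(chrom)
            if d is not None and d < min_density:
                excluded[chrom] = (
                    f"SNP density {d:g}/kb in species {label} < {min_density:g}"
                )
                break
    return excluded


def compare_maps(maps_a: dict, maps_b: dict, window_size: int = 50_000,
                 chrom_lengths: dict | None = None,
                 densities_a: dict | None = None,
                 densities_b: dict | None = None,
                 min_density: float = 0.0) -> MapComparison:
    """Full comparison: density mask, window alignment, tau, difference."""
    excluded = {}
    if densities_a is not None and densities_b is not None:
        excluded = snp_density_mask(densities_a, densities_b, min_density)
        maps_a = {c: m for c, m in maps_a.items() if c not in excluded}
        maps_b = {c: m for c, m in maps_b.items() if c not in excluded}
    pairs = align_windows(maps_a, maps_b, window_size, chrom_lengths)
    gw, per_chrom, skipped = conservation_stats(pairs)
    excluded.update(skipped)
    return MapComparison(window_size, pairs, gw, per_chrom, excluded)


def subsample_consistency(pairs: pd.DataFrame, fraction: float = 0.5,
                          seed: int = 0) -> CorrelationResult:
    """Conservation tau recomputed from a random subsample of windows — a
    map-level analogue of re-running one species at a smaller sample size
    to check that the correlation is not an artefact of unequal power."""
    rng = np.random.default_rng(seed)
    n = len(pairs)
    take = rng.choice(n, size=max(3, int(round(fraction * n))), replace=False)
    sub = pairs.iloc[np.sort(take)]
    return kendall_tau_b(sub["rate_a"], sub["rate_b"])
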