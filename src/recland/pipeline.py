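"""End-to-end assembly: window tables and study-level result bundles.

Glue that runs the whole analysis on a map + annotation + tracks bundle
(real files or a synthetic study) and returns tidy tables: the per-window
statistic matrix used by the correlation analyses, per-chromosome
summaries, and the standard contrast tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import landscape
from .cpg import detect_islands_genome
from .features import (FeatureSet, mean_rate_by_feature, tile_windows,
                       window_density_coverage)
from .ratemap import summarize_genome
from .simulate import SimulationConfig, simulate_study
from .tracks import gc_content_windows, pi_windows


def build_window_table(maps: dict, chrom_lengths: dict, window_size: int,
                       genome: dict | None = None,
                       cpgi: FeatureSet | None = None,
                       genes: FeatureSet | None = None,
                       rts: FeatureSet | None = None,
                       sites=None,
                       min_covered_fraction: float = 0.5,
                       pi_min_called_bp: int = 20_000,
                       pi_min_data_fraction: float = 0.7) -> pd.DataFrame:
    """Window table with rate plus whichever tracks are available.

    Columns: ``rate_cM_Mb`` always; ``gc`` (needs sequences), ``pi`` (needs
    genotypes), ``cpgi_density``/``cpgi_coverage``, ``gene_density``/
    ``gene_coverage``, and per-RT-family coverage columns when the
    corresponding inputs are given.
    """
    windows = tile_windows(chrom_lengths, window_size)
    frames = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        m = maps.get(chrom)
        sub = wsub.copy()
        if m is not None:
            w = m.window_rates(window_size, min_covered_fraction,
                               chrom_lengths[chrom])
            sub["rate_cM_Mb"] = w["rate_cM_Mb"].to_numpy()
            sub["covered_fraction"] = w["covered_fraction"].to_numpy()
        else:
            sub["rate_cM_Mb"] = np.nan
            sub["covered_fraction"] = 0.0
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    if genome is not None:
        out["gc"] = gc_content_windows(genome, out)
    if sites is not None:
        out["pi"] = pi_windows(sites, out, min_called_bp=pi_min_called_bp,
                               min_data_fraction=pi_min_data_fraction)
    if cpgi is not None:
        out["cpgi_density"] = window_density_coverage(cpgi, out, "density")
        out["cpgi_coverage"] = window_density_coverage(cpgi, out, "coverage")
    if genes is not None:
        gene_only = genes.select("gene")
        out["gene_density"] = window_density_coverage(gene_only, out, "density")
        out["gene_coverage"] = window_density_coverage(gene_only, out, "coverage")
    if rts is not None:
        for fam in sorted(rts.df["category"].unique()):
            out[f"{fam}_coverage"] = window_density_coverage(
                rts.select(fam), out, "coverage")
    return out


def run_study(config: SimulationConfig | None = None, seed: int = 0,
              window_size: int = 200_000, with_diversity: bool = True,
              with_sequence: bool = True, detect_cpgi: bool = False) -> dict:
    """Simulate a study and run the core analyses on it.

    Returns a dict with the simulation bundle plus ``windows`` (the window
    statistic table), ``summaries`` (per-chromosome table + objects),
    ``size_rate`` (CorrelationResult), ``micro_macro`` (contrast dict) and
    ``taus`` (rate-vs-track Kendall results).  ``detect_cpgi`` switches the
    window CpGi column from planted truth to islands re-detected from the
    sequence.
    """
    config = config or SimulationConfig()
    study = simulate_study(config, seed, with_diversity=with_diversity,
                           with_sequence=with_sequence)
    genome = study["genome"]
    cpgi = (detect_islands_genome(genome.sequences) if detect_cpgi
            else genome.cpgi)
    windows = build_window_table(
        study["maps"], config.chrom_lengths, window_size,
        genome=genome.sequences if with_sequence else None,
        cpgi=cpgi, genes=genome.genes,
        rts=genome.rts, sites=study["sites"],
    )
    from .ratemap import chromosome_summary
    summaries = [
        chromosome_summary(study["maps"][c], config.chrom_lengths[c],
                           micro_threshold=config.micro_threshold)
        for c in study["maps"]
    ]
    taus = {}
    for col in ("pi", "gc", "cpgi_density"):
        if col in windows:
            taus[col] = landscape.kendall_tau_b(windows["rate_cM_Mb"],
                                                windows[col])
    study.update({
        "config": config,
        "windows": windows,
        "summaries": summaries,
        "summary_table": summarize_genome(
            study["maps"], config.chrom_lengths,
            micro_threshold=config.micro_threshold),
        "size_rate": landscape.size_rate_correlation(summaries),
        "micro_macro": landscape.micro_macro_contrast(summaries),
        "taus": taus,
    })
    return study


def genome_wide_mean_rate(maps: dict, cM_per_Mb: bool = True) -> float:
    """Coverage-weighted mean rate over a whole map collection."""
    mass = sum(m.total_mass for m in maps.values())
    cov = sum(m.covered_bp for m in maps.values())
    r = mass / cov if cov else float("nan")
    return r * 1e8 if cM_per_Mb else r
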