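"""Seed-controlled synthetic study generator with known ground truth.

The generator emulates the statistical structure the landscape analyses
assume in an avian-like genome, at a scale that keeps a full analysis run
cheap:

* 8 chromosomes spanning macro (>= 20 Mb) and micro (< 20 Mb) sizes;
* a per-chromosome baseline rate proportional to ``length ** -beta``
  (shorter chromosomes recombine more);
* telomeric rate elevation with a sharp terminal drop, and a central
  recombination desert on macrochromosomes;
* gene models (gene/mRNA/exon/UTR, stranded), CpG islands planted as
  dense CG runs (preferentially in high-rate regions and in promoters),
  and LTR/LINE/SINE retrotransposon intervals;
* local rate boosts tied to CpG islands/promoters and to LINEs inside
  promoters (the planted association the contrast analyses must recover);
* multiplicative log-normal rate noise;
* window GC content coupled to the deterministic rate field;
* a nucleotide-diversity track linearly coupled to the rate, realised as
  biallelic SNP genotypes whose windowed pi recovers the target in
  expectation;
* a correlated sister-species map sharing interval structure, with a
  configurable per-chromosome log-scale correlation.

Everything is driven by one integer seed through ``numpy``'s
``SeedSequence`` spawning, so identical config + seed give identical
outputs, byte-for-byte when written to disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSet, derive_promoters, derive_tss, tile_windows
from .ratemap import RateMap
from .tracks import SiteTable

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Rates are per-bp per-generation; lengths in bp.  The defaults describe
    an avian-like genome scaled down roughly five-fold, with the size
    effect carried by ``beta`` (baseline ~ length^-beta).
    """

    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 40_000_000, "chr2": 30_000_000, "chr3": 22_000_000,
        "chr4": 14_000_000, "chr5": 9_000_000, "chr6": 6_000_000,
        "chr7": 4_000_000, "chr8": 2_000_000,
    })
    micro_threshold: int = 20_000_000

    # rate field
    r0: float = 3e-8               # baseline rate at the reference length
    length_ref: float = 3e7
    beta: float = 0.5              # baseline ~ (L / length_ref) ** -beta
    micro_boost: float = 1.0       # extra multiplicative factor, micros only
    telomere_factor: float = 4.0
    telomere_frac: float = 0.10    # fraction of L near each end elevated
    terminal_drop_factor: float = 0.1
    terminal_frac: float = 0.005   # very ends where the rate collapses
    desert_factor: float = 0.2     # macro-only central desert
    desert_frac: float = 0.2
    cpgi_boost: float = 2.0        # applies to CpGi and promoter cells
    line_promoter_boost: float = 2.0
    noise_sd: float = 0.5          # log-normal cell noise (mean-corrected)
    cell_size: int = 1000
    gap_fraction: float = 0.0      # fraction of cells emitted as "no estimate"

    # annotation
    gene_per_mb: float = 8.0
    gene_length: tuple = (5_000, 30_000)
    exons_per_gene: tuple = (3, 8)
    utr_length: int = 200
    promoter_length: int = 2_000
    cpgi_per_mb: float = 8.0       # background islands (placement ~ rate field)
    promoter_cpgi_fraction: float = 0.6
    island_n_cpg: tuple = (30, 70)
    rt_families: dict = field(default_factory=lambda: {
        # family: (elements per Mb, min length, max length)
        "LTR": (5.0, 1_000, 5_000),
        "LINE": (20.0, 500, 5_000),
        "SINE": (30.0, 100, 300),
    })

    # sequence composition
    gc_base: float = 0.42
    gc_slope: float = 0.04         # GC shift per SD of log deterministic rate

    # diversity coupling: pi = pi_a + pi_b * rate_cM_Mb + noise
    pi_a: float = 0.002
    pi_b_per_cM_Mb: float = 5e-4
    pi_noise_sd: float = 3e-4
    pi_window: int = 200_000
    n_samples: int = 10            # diploid individuals
    missing_rate: float = 0.02

    # sister species map
    sister_rho: float | dict = 0.6
    sister_mean_cM_Mb: float = 2.0

    def classes(self) -> dict:
        return {c: ("micro" if L < self.micro_threshold else "macro")
                for c, L in self.chrom_lengths.items()}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["rt_families"] = {k: tuple(v) for k, v in d.get("rt_families", {}).items()}
        for key in ("gene_length", "exons_per_gene", "island_n_cpg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Realised ground truth, sufficient to predict every expected effect
    direction in recovery tests."""

    config: SimulationConfig
    base_rates: dict               # chrom -> deterministic baseline r
    classes: dict                  # chrom -> micro|macro
    n_genes: dict
    n_islands: dict
    n_rts: dict                    # chrom -> {family: count}
    sister_rho: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "config": json.loads(self.config.to_json()),
            "base_rates": self.base_rates,
            "classes": self.classes,
            "n_genes": self.n_genes,
            "n_islands": self.n_islands,
            "n_rts": self.n_rts,
            "sister_rho": self.sister_rho,
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticGenome:
    """In-memory synthetic genome: sequences plus cross-consistent
    annotation layers."""

    config: SimulationConfig
    sequences: dict                # chrom -> uint8 codes
    genes: FeatureSet              # gene/mRNA/exon/UTR records
    cpgi: FeatureSet               # planted islands (ground truth spans)
    rts: FeatureSet                # LTR/LINE/SINE intervals
    tss: FeatureSet
    promoters: FeatureSet          # split with/without CpGi

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.config.chrom_lengths)

    def write_fasta(self, path):
        from .tracks import write_fasta
        write_fasta(self.sequences, path)

    def write_gff3(self, path):
        df = self.genes.df
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, row in df.iterrows():
                fh.write(
                    f"{row['chrom']}\trecland_sim\t{row['category']}\t"
                    f"{row['start'] + 1}\t{row['end']}\t.\t{row['strand']}\t.\t"
                    f"ID={row['id']}\n"
                )

    def write_beds(self, outdir):
        import os
        self.cpgi.write_bed(os.path.join(outdir, "cpgi.bed"))
        self.rts.write_bed(os.path.join(outdir, "rts.bed"))
        self.promoters.write_bed(os.path.join(outdir, "promoters.bed"))


# --------------------------------------------------------------- rate field
def _deterministic_factor(config: SimulationConfig, chrom: str,
                          n_cells: int) -> np.ndarray:
    """Per-cell deterministic rate multiplier: baseline x telomere x desert."""
    L = config.chrom_lengths[chrom]
    x = (np.arange(n_cells) + 0.5) * config.cell_size
    x = np.minimum(x, L - 0.5)
    d_end = np.minimum(x, L - x)
    factor = np.ones(n_cells)
    factor[d_end < config.telomere_frac * L] *= config.telomere_factor
    factor[d_end < config.terminal_frac * L] *= config.terminal_drop_factor
    if L >= config.micro_threshold:
        centre = np.abs(x - L / 2.0) < (config.desert_frac * L / 2.0)
        factor[centre] *= config.desert_factor
    base = config.r0 * (L / config.length_ref) ** (-config.beta)
    if L < config.micro_threshold:
        base *= config.micro_boost
    return base * factor


def _cells_overlapping(intervals: np.ndarray, n_cells: int,
                       cell_size: int) -> np.ndarray:
    """Boolean per-cell mask: cell overlaps any of the (n, 2) intervals."""
    mask = np.zeros(n_cells, dtype=bool)
    for s, e in intervals:
        c0 = max(int(s) // cell_size, 0)
        c1 = min((int(e) - 1) // cell_size + 1, n_cells)
        if c1 > c0:
            mask[c0:c1] = True
    return mask


# ------------------------------------------------------------------- genome
def simulate_genome(config: SimulationConfig, seed: int,
                    with_sequence: bool = True) -> SyntheticGenome:
    """Sequences + cross-consistent gene/CpGi/RT annotations.

    Placement intensity of background CpG islands follows the deterministic
    rate field, mirroring the empirical co-location of CpG islands with
    high-recombination (GC-rich, telomeric, micro) regions; a configured
    fraction of promoters additionally carries an island.

    ``with_sequence=False`` skips base-level sequence synthesis (annotation
    coordinates are unaffected — placement only depends on the rate field),
    for analyses that need maps and features but no sequence tracks.
    """
    ss = np.random.SeedSequence([int(seed), 11])
    rngs = {c: np.random.default_rng(child)
            for c, child in zip(config.chrom_lengths,
                                ss.spawn(len(config.chrom_lengths)))}
    cell = config.cell_size

    # global standardisation of the log deterministic field for GC coupling
    factors = {}
    for chrom, L in config.chrom_lengths.items():
        n_cells = -(-L // cell)
        factors[chrom] = _deterministic_factor(config, chrom, n_cells)
    all_log = np.log(np.concatenate(list(factors.values())))
    mu_log, sd_log = all_log.mean(), max(all_log.std(), 1e-9)

    sequences, gene_rows, cpgi_rows, rt_rows = {}, [], [], []
    for chrom, L in config.chrom_lengths.items():
        rng = rngs[chrom]
        fac = factors[chrom]
        z = (np.log(fac) - mu_log) / sd_log
        gc = np.clip(config.gc_base + config.gc_slope * z, 0.25, 0.65)
        if with_sequence:
            g_per_base = np.repeat(gc.astype(np.float32), cell)[:L]
            u = rng.random(L, dtype=np.float32)
            # thresholds split [0,1) into C | G | A | T with P(C)=P(G)=g/2
            idx = (u >= g_per_base / 2).astype(np.uint8)
            idx += u >= g_per_base
            idx += u >= (1 + g_per_base) / 2
            codes = np.array([1, 2, 0, 3], dtype=np.uint8)[idx]
        else:
            codes = np.empty(0, dtype=np.uint8)

        # ---- genes (non-overlapping, stranded, with exons and UTRs)
        n_genes = rng.poisson(config.gene_per_mb * L / 1e6)
        cand = np.sort(rng.integers(0, max(L - config.gene_length[1], 1),
                                    size=max(n_genes, 0)))
        prev_end = -10_000
        gid = 0
        for s in cand:
            glen = int(rng.integers(*config.gene_length))
            e = min(s + glen, L)
            if s < prev_end + 2_000 or e - s < config.gene_length[0]:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            name = f"{chrom}_g{gid}"
            gene_rows.append((chrom, s, e, strand, "gene", name))
            gene_rows.append((chrom, s, e, strand, "mRNA", f"{name}.t1"))
            n_ex = int(rng.integers(*config.exons_per_gene))
            cuts = np.sort(rng.choice(np.arange(s + 50, e - 50), size=2 * n_ex - 2,
                                      replace=False)) if e - s > 200 else []
            bounds = np.concatenate([[s], np.asarray(cuts), [e]])
            for k in range(0, len(bounds) - 1, 2):
                ex_s, ex_e = int(bounds[k]), int(bounds[k + 1])
                if ex_e > ex_s:
                    gene_rows.append((chrom, ex_s, ex_e, strand, "exon",
                                      f"{name}.e{k // 2 + 1}"))
            u5 = (s, min(s + config.utr_length, e)) if strand == "+" else \
                 (max(e - config.utr_length, s), e)
            u3 = (max(e - config.utr_length, s), e) if strand == "+" else \
                 (s, min(s + config.utr_length, e))
            gene_rows.append((chrom, u5[0], u5[1], strand, "five_prime_UTR",
                              f"{name}.u5"))
            gene_rows.append((chrom, u3[0], u3[1], strand, "three_prime_UTR",
                              f"{name}.u3"))
            prev_end = e

        # ---- CpG islands: background (intensity ~ rate field) + promoter
        n_bg = rng.poisson(config.cpgi_per_mb * L / 1e6)
        p_cell = fac / fac.sum()
        isl_cells = rng.choice(fac.size, size=n_bg, p=p_cell)
        isl_starts = isl_cells * cell + rng.integers(0, cell, size=n_bg)
        prom_sites = [(r[1], r[2], r[3]) for r in gene_rows
                      if r[0] == chrom and r[4] == "mRNA"]
        for (g_start, g_end, strand) in prom_sites:
            if rng.random() < config.promoter_cpgi_fraction:
                # inside the promoter: upstream of the strand-aware TSS
                pos = g_start - 700 if strand == "+" else g_end + 300
                isl_starts = np.append(isl_starts, max(pos, 1))
        for s in np.sort(isl_starts):
            n_cpg = int(rng.integers(*config.island_n_cpg))
            spacings = rng.integers(2, 5, size=n_cpg - 1)
            length = int(spacings.sum()) + 2
            s = int(min(s, L - length - 1))
            if s < 0:
                continue
            if with_sequence:
                # overwrite sequence with the dense CpG run
                pos = s
                for i in range(n_cpg):
                    codes[pos] = 1
                    codes[pos + 1] = 2
                    if i < n_cpg - 1:
                        gap = int(spacings[i]) - 2
                        if gap > 0:
                            # AT filler so no accidental CG forms in the gap
                            codes[pos + 2:pos + 2 + gap] = rng.choice(
                                [0, 3], size=gap
                            ).astype(np.uint8)
                        pos += int(spacings[i])
            cpgi_rows.append((chrom, s, s + length, "+", "CpGi",
                              f"{chrom}_i{len(cpgi_rows)}"))

        # ---- retrotransposons
        for fam, (per_mb, lo, hi) in config.rt_families.items():
            n_rt = rng.poisson(per_mb * L / 1e6)
            starts = rng.integers(0, max(L - hi, 1), size=n_rt)
            lens = rng.integers(lo, hi + 1, size=n_rt)
            for s, ln in zip(np.sort(starts), lens):
                rt_rows.append((chrom, int(s), int(min(s + ln, L)), "+", fam,
                                f"{chrom}_{fam}{len(rt_rows)}"))
        sequences[chrom] = codes

    cols = ["chrom", "start", "end", "strand", "category", "id"]
    genes = FeatureSet(pd.DataFrame(gene_rows, columns=cols), validate=False)
    cpgi = FeatureSet(pd.DataFrame(cpgi_rows, columns=cols), validate=False)
    rts = FeatureSet(pd.DataFrame(rt_rows, columns=cols), validate=False)
    tss = derive_tss(genes.select("mRNA"))
    promoters = derive_promoters(tss, config.promoter_length, cpgi,
                                 config.chrom_lengths)
    return SyntheticGenome(config, sequences, genes, cpgi, rts, tss, promoters)


# ----------------------------------------------------------------- rate map
def simulate_rate_map(config: SimulationConfig, genome: SyntheticGenome,
                      seed: int):
    """Piecewise-constant rate maps + realised truth.

    ``r(cell) = base(L) * telomere * desert * boosts * exp(N(0, sd^2))``
    with the log-normal noise mean-corrected so boosts act on expectations.
    """
    ss = np.random.SeedSequence([int(seed), 23])
    children = ss.spawn(len(config.chrom_lengths))
    cell = config.cell_size
    maps = {}
    base_rates, n_rts = {}, {}
    for (chrom, L), child in zip(config.chrom_lengths.items(), children):
        rng = np.random.default_rng(child)
        n_cells = -(-L // cell)
        r = _deterministic_factor(config, chrom, n_cells).copy()

        boosted = np.zeros(n_cells, dtype=bool)
        for fs in (genome.cpgi, genome.promoters):
            sub = fs.df[fs.df["chrom"] == chrom]
            boosted |= _cells_overlapping(
                sub[["start", "end"]].to_numpy(), n_cells, cell)
        r[boosted] *= config.cpgi_boost

        # LINEs intersected with promoters
        prom = genome.promoters.df[genome.promoters.df["chrom"] == chrom]
        lines = genome.rts.df[(genome.rts.df["chrom"] == chrom)
                              & (genome.rts.df["category"] == "LINE")]
        if len(prom) and len(lines):
            pm = _cells_overlapping(prom[["start", "end"]].to_numpy(),
                                    n_cells, cell)
            lm = _cells_overlapping(lines[["start", "end"]].to_numpy(),
                                    n_cells, cell)
            r[pm & lm] *= config.line_promoter_boost

        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, n_cells)
            r = r * np.exp(noise - config.noise_sd ** 2 / 2.0)

        starts = np.arange(n_cells, dtype=np.int64) * cell
        ends = np.minimum(starts + cell, L)
        if config.gap_fraction > 0:
            keep = rng.random(n_cells) >= config.gap_fraction
            starts, ends, r = starts[keep], ends[keep], r[keep]
        maps[chrom] = RateMap(chrom, starts, ends, r)
        base = config.r0 * (L / config.length_ref) ** (-config.beta)
        if L < config.micro_threshold:
            base *= config.micro_boost
        base_rates[chrom] = base
        n_rts[chrom] = dict(
            genome.rts.df[genome.rts.df["chrom"] == chrom]["category"]
            .value_counts()
        )
    truth = SyntheticTruth(
        config=config,
        base_rates=base_rates,
        classes=config.classes(),
        n_genes={c: int((genome.genes.df["chrom"] == c)
                        .loc[genome.genes.df["category"] == "gene"].sum())
                 for c in config.chrom_lengths},
        n_islands={c: int((genome.cpgi.df["chrom"] == c).sum())
                   for c in config.chrom_lengths},
        n_rts={c: {k: int(v) for k, v in d.items()} for c, d in n_rts.items()},
        sister_rho={c: float(config.sister_rho[c]
                             if isinstance(config.sister_rho, dict)
                             else config.sister_rho)
                    for c in config.chrom_lengths},
    )
    return maps, truth


# ------------------------------------------------------------------- sister
def simulate_sister_map(maps: dict, rho, seed: int,
                        mean_cM_Mb: float = 2.0) -> dict:
    """Correlated sister-species map on the same interval structure.

    Per chromosome, the standardized log rate of the focal map is mixed
    with an independent Gaussian field at correlation ``rho`` (scalar or
    per-chromosome dict), then rescaled to ``mean_cM_Mb`` on the linear
    scale.
    """
    ss = np.random.SeedSequence([int(seed), 37])
    raw = {}
    for (chrom, m), child in zip(maps.items(), ss.spawn(len(maps))):
        rng = np.random.default_rng(child)
        rc = float(rho[chrom] if isinstance(rho, dict) else rho)
        if not 0.0 <= rc <= 1.0:
            raise SimulationError("sister rho must lie in [0, 1]")
        logr = np.log(np.maximum(m.rates, 1e-300))
        sd = logr.std()
        z = (logr - logr.mean()) / max(sd, 1e-12)
        eps = rng.normal(0.0, 1.0, z.size)
        zb = rc * z + np.sqrt(max(1.0 - rc ** 2, 0.0)) * eps
        # keep the chromosome's own log-location so cross-chromosome rate
        # ratios survive; rho = 1 with zero noise is then exactly linear
        raw[chrom] = np.exp(zb * sd + logr.mean())
    total_mass = sum(np.sum(raw[c] * (maps[c].ends - maps[c].starts))
                     for c in maps)
    total_len = sum(int(np.sum(maps[c].ends - maps[c].starts)) for c in maps)
    scale = (mean_cM_Mb * 1e-8) / (total_mass / total_len)
    return {c: RateMap(c, maps[c].starts.copy(), maps[c].ends.copy(),
                       raw[c] * scale)
            for c in maps}


# ---------------------------------------------------------------- diversity
def _sfs_expected_het(n_haplotypes: int):
    """Allele-count distribution ~ 1/j (neutral SFS) and the expected
    per-SNP unbiased heterozygosity under it."""
    H = n_haplotypes
    j = np.arange(1, H)
    w = 1.0 / j
    w /= w.sum()
    c = 2.0 * (j / H) * (1.0 - j / H) * H / (H - 1.0)
    return j, w, float(np.sum(w * c))


def simulate_diversity(maps: dict, config: SimulationConfig, seed: int):
    """Biallelic SNP genotypes whose windowed pi tracks the rate map.

    Per ``pi_window`` window the target is
    ``pi = pi_a + pi_b * rate_cM_Mb + N(0, pi_noise_sd)`` (truncated at a
    small positive floor); SNP counts and frequencies are drawn so windowed
    pi recovers the target in expectation under a 1/j allele-frequency
    spectrum.

    Returns ``(SiteTable, targets)`` where ``targets`` is the per-window
    target table (chrom, start, end, rate_cM_Mb, pi_target).
    """
    if config.pi_b_per_cM_Mb < 0:
        raise SimulationError("pi coupling slope must be >= 0")
    ss = np.random.SeedSequence([int(seed), 53])
    H = 2 * config.n_samples
    j_vals, w, e_het = _sfs_expected_het(H)
    positions, genotypes, target_rows = {}, {}, []
    for (chrom, m), child in zip(maps.items(), ss.spawn(len(maps))):
        rng = np.random.default_rng(child)
        L = m.span
        wins = m.window_rates(config.pi_window, min_covered_fraction=0.0,
                              chrom_length=L)
        rate = np.nan_to_num(wins["rate_cM_Mb"].to_numpy())
        target = (config.pi_a + config.pi_b_per_cM_Mb * rate
                  + rng.normal(0.0, config.pi_noise_sd, rate.size))
        target = np.maximum(target, 1e-4)
        ws = wins["start"].to_numpy()
        we = wins["end"].to_numpy()
        counts = np.round(target * (we - ws) / e_het).astype(int)
        pos_list, j_list = [], []
        for s, e, mcount in zip(ws, we, counts):
            if mcount <= 0:
                continue
            p = np.unique(rng.integers(s, e, size=mcount))
            pos_list.append(p)
            j_list.append(rng.choice(j_vals, size=p.size, p=w))
        if not pos_list:
            continue
        pos = np.concatenate(pos_list)
        jarr = np.concatenate(j_list)
        # assign j alternate alleles to random haplotypes, per site
        scores = rng.random((pos.size, H))
        rank = scores.argsort(axis=1).argsort(axis=1)
        alt = rank < jarr[:, None]
        gt = (alt[:, 0::2].astype(np.int8) + alt[:, 1::2].astype(np.int8))
        if config.missing_rate > 0:
            miss = rng.random(gt.shape) < config.missing_rate
            gt[miss] = 3
        positions[chrom] = pos
        genotypes[chrom] = gt
        target_rows.append(pd.DataFrame({
            "chrom": chrom, "start": ws, "end": we,
            "rate_cM_Mb": rate, "pi_target": target,
        }))
    samples = [f"ind{i + 1}" for i in range(config.n_samples)]
    targets = (pd.concat(target_rows, ignore_index=True)
               if target_rows else pd.DataFrame())
    return SiteTable(positions, genotypes, samples), targets


def write_vcf(sites: SiteTable, path, chrom_lengths: dict | None = None):
    """Write the site table as a minimal GT-only VCF 4.2 text file."""
    gtstr = np.array(["0/0", "0/1", "1/1", "./."])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for c, L in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(L)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sites.samples) + "\n")
        for chrom in sites.positions:
            pos = sites.positions[chrom]
            gt = sites.genotypes[chrom]
            cells = gtstr[gt]
            for i in range(pos.size):
                fh.write(f"{chrom}\t{pos[i] + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(cells[i]) + "\n")


def simulate_study(config: SimulationConfig, seed: int,
                   with_diversity: bool = True,
                   with_sequence: bool = True):
    """One full synthetic study: genome, maps, sister map, diversity.

    Returns a dict with keys ``genome``, ``maps``, ``truth``, ``sister``,
    ``sites``, ``pi_targets`` (the last two None when ``with_diversity``
    is off).
    """
    genome = simulate_genome(config, seed, with_sequence=with_sequence)
    maps, truth = simulate_rate_map(config, genome, seed)
    sister = simulate_sister_map(maps, config.sister_rho, seed,
                                 config.sister_mean_cM_Mb)
    sites = targets = None
    if with_diversity:
        sites, targets = simulate_diversity(maps, config, seed)
    return {
        "genome": genome, "maps": maps, "truth": truth, "sister": sister,
        "sites": sites, "pi_targets": targets,
    }
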