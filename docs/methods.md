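# Methods

`recland` analyses historical (linkage-disequilibrium-based) recombination
landscapes: piecewise-constant per-generation rate maps of the kind
produced by LD-based estimators such as Pyrho, together with the genomic
features those rates co-vary with in birds and other PRDM9-lacking
vertebrates. This note documents the models, conventions, numerical
choices and limitations; everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Rate-map calculus

A rate map is a set of sorted, non-overlapping, half-open intervals
`[start, end)` with a per-bp per-generation crossover rate `r >= 0`.
Units: `1 cM/Mb = 1e-8` in `r`; the genetic length of a region is
`100 * sum(r_i * len_i)` cM; the expected crossovers per transmitted
gamete for a chromosome is `mean(r) * length`.

Three conventions matter and are fixed package-wide:

* **Gaps are missing data, never rate 0.** LD-based estimators emit rates
  only between informative SNP pairs; zero-filling gaps would bias every
  windowed mean downward. Gaps are excluded from all denominators; a
  window or feature entirely inside a gap is `NaN`.
* **Coordinates are 0-based half-open** internally; the map reader
  accepts 1-based input behind a flag, GFF3 is converted on ingest.
* **Windows tile from position 0**; the last partial window is kept with
  its true span, and windows below a minimum covered fraction (default
  0.5) are flagged missing rather than silently reported.

Weighted region means are computed from cumulative mass/coverage arrays
(`O(log n)` per query, vectorised), which makes window-mass conservation
(`sum over windows of rate x covered bp == total map mass`) hold to
machine precision by construction — the acceptance script measures the
worst relative error over random maps.

Per-chromosome summaries include the population-scaled rate
`rho = 4 * Ne * mean(r)`. `Ne` comes from the population mutation
parameter as `Ne = theta / (4 * mu)` by default (`theta = 4 Ne mu` is the
standard definition); a `factor=1` option reproduces the "theta divided
by mutation rate" convention some pipelines use, since published
descriptions are sometimes ambiguous about whether their theta already
absorbs the factor 4. Default `mu = 4.6e-9` per bp per generation, the
collared flycatcher pedigree estimate commonly borrowed for songbirds.
Chromosomes shorter than 20 Mb are classed as microchromosomes
(configurable).

## Feature geometry

Annotation categories follow avian genome practice: genes, mRNAs, exons,
UTRs, TSS (the strand-aware first base of an mRNA, duplicates across
isoforms collapsed), promoters (the 2 kb immediately upstream of a TSS,
clipped at chromosome bounds and split by >= 1 bp CpG-island overlap),
intergenic space (complement of gene spans — introns are genic; a
"non-exonic" variant is provided for the looser reading), and the three
retrotransposon families LTR / LINE / SINE. Unknown strand is treated as
"+" with a logged warning.

Window statistics use bedtools-style semantics: *density* counts a
feature once in every window it overlaps; *coverage* is the fraction of
window bases under the union of features. Overlap splits
(with/without a retrotransposon family) use the >= 1 bp default.

## Tracks

**GC** is `(G+C)/(A+C+G+T)` per window, case-insensitive, ambiguity
codes excluded from the denominator.

**Nucleotide diversity** uses the unbiased per-site heterozygosity
`2 p (1-p) n/(n-1)` summed over biallelic SNPs and divided by the
window's callable length, following the windowed-scan convention.
Missingness rules mirror those scans: a window needs >= 20 kb callable
(default) and >= 70% of individuals meeting the per-window callable
floor. With no per-individual all-sites mask available, an individual's
callable bp in a window is approximated as the window's callable bp times
that individual's non-missing genotype fraction at the window's SNPs;
this is exact when missingness is homogeneous within a window and is the
only approximation in the track.

**Complexity (Cx)** is a genome-uniqueness proxy in [0, 1]: the fraction
of positions whose forward k-mer (k = 16 by default, 2-bit packed)
occurs exactly once among all forward k-mers of the genome. 1 means
fully unique sequence, 0 a perfect repeat; positions whose k-mer touches
an ambiguous base are undefined. This deliberately replaces match-length
complexity statistics with an exactly testable quantity that preserves
the same orientation and range; it is computed on the analysis window
grid rather than on overlapping windows.

## CpG islands

Islands are detected by distance clustering: CpG positions are recorded
(the C of each CG, overlapping scan); the clustering threshold is the
integer-floored median of consecutive CpG distances on the chromosome; a
candidate island is a maximal run of >= 2 CpGs whose consecutive
distances all stay at or below the threshold, spanning first C to last
G. Significance assumes CpGs form a homogeneous point process with
per-position rate `p = n_cpg / sequence_length`; spacings are then
i.i.d. shifted-geometric and the total intra-island distance `D` is a
shifted negative binomial with `n_cpg - 1` components, giving
`p-value = P(D' <= D)`. Note the rate is the *genome-wide* CpG density,
not the reciprocal of the mean observed spacing: on sequences whose CpGs
sit mostly inside islands the two differ drastically, and only the
former judges clusters against the background rather than against
themselves. Retained islands satisfy length >= 50 bp and p <= 1e-5
(both configurable); island boundaries always coincide with CpG
positions and retained islands never overlap.

## Rank statistics

All association analyses use rank statistics because recombination rates
are roughly exponentially distributed: Kendall's tau-b (tie-corrected;
two-sided p from the normal approximation with tie-corrected variance),
partial Kendall correlations via the inverse of the pairwise tau matrix
(`partial_ij = -Om_ij / sqrt(Om_ii Om_jj)`, p from
`z = partial * sqrt(9 m (m-1) / (2 (2m+5)))`, `m = n - (k-2)` — the
ppcor convention), Wilcoxon rank-sum with midranks (exact by full
enumeration when `n_a + n_b <= 12`, else normal approximation with tie
correction and continuity correction), Welch's t for class means, and
Holm (default) or Benjamini–Hochberg multiplicity adjustment — Holm
because it controls FWER without independence assumptions for the small
families of contrasts used here. Simple correlations delete missing
pairs pairwise; partial correlations listwise (matrix inversion needs a
common sample). A useful consequence exercised by the tests: strictly
increasing transforms (log chromosome size, square-root rates) cannot
change tau.

## Composite analyses

* **Size–rate**: tau between log10 chromosome length and mean cM/Mb
  rate; micro/macro contrast by Welch's t on class means.
* **Distance profiles**: mean windowed rate in 5 kb bins spanning
  ±200 kb from anchors. TSS anchors are strand-oriented (the offset axis
  mirrors for "-" features); CpG-island anchors use the island start
  without strand logic, and the mean rate over the anchors' own spans is
  reported separately as an "inside-anchor" value. Bands are
  mean ± 1.96 SE across anchors — a per-bin normal approximation, not a
  smoother. Flank trends are separate up/downstream taus over ±50 kb.
* **Category contrasts**: per-feature mean rates per category against
  the genome-wide 200 kb window rate distribution (Wilcoxon, Holm
  across categories).
* **RT-overlap contrasts**: per (category, family), rates of features
  with vs without >= 1 bp overlap (Wilcoxon); empty cells are reported
  missing, not raised.

## Cross-species conservation

Both maps must share one reference coordinate system. Identical window
tilings are applied to both; windows defined in both species are paired;
conservation is tau-b genome-wide and per chromosome (units with < 3
pairs are skipped with a recorded reason). The difference track is
`log10(rate_A) - log10(rate_B)` per 50 kb window; windows with a
non-positive rate are dropped and counted rather than epsilon-padded,
because any epsilon would dominate the tails of the difference
distribution. Chromosomes can be pre-excluded by a per-species SNP
density threshold, and a subsample-consistency mode recomputes tau from
a random window subsample to mimic equal-sample-size robustness checks.

## Synthetic study generator

The generator produces a genome whose statistical structure matches what
the analyses assume, with all couplings known:

* 8 chromosomes, 2–40 Mb (about five-fold scaled down from avian
  proportions), macro/micro split at 20 Mb;
* baseline rate `r0 (L/L_ref)^-beta` with `beta = 0.5` — shorter
  chromosomes recombine more; an optional explicit micro-boost factor
  carries the class effect when `beta` is switched off;
* telomeric elevation (x4 over the outer 10% of each end), a sharp
  terminal collapse (x0.1 over the outer 0.5%), and a central desert
  (x0.2 over the middle 20%) on macrochromosomes only;
* gene models with exons/UTRs and strands; CpG islands planted as dense
  CG runs (30–70 CpGs, 2–4 bp spacings), placed preferentially where the
  deterministic rate field is high plus in 60% of promoters — mirroring
  the empirical co-location of islands with GC-rich high-recombination
  regions; LTR/LINE/SINE intervals at 5/20/30 per Mb;
* local boosts: x2 at CpG islands and promoters, x2 where LINEs
  intersect promoters (the planted association the contrast analyses
  must recover);
* log-normal multiplicative noise per 1 kb cell (sd 0.5 on the log
  scale, mean-corrected so boosts act on expectations); maps are emitted
  as piecewise-constant 1 kb intervals. Rate fields are generated
  directly rather than via coalescent simulation — the package tests the
  downstream analysis, not LD inference;
* window GC probability `0.42 + 0.04 z` (clipped to [0.25, 0.65]) with
  `z` the standardised log deterministic rate, so GC co-varies with rate
  but not with its noise;
* diversity `pi = 0.002 + 5e-4 * rate_cM_Mb + N(0, 3e-4)` per 200 kb
  window, realised as biallelic SNPs with allele counts drawn from a
  neutral 1/j spectrum over 10 diploids and placed so that windowed pi
  recovers the target in expectation (about 16 SNPs/kb at the default
  rates — the density range reported for songbird cohorts); 2% missing
  genotypes;
* a sister-species map built per chromosome by mixing the standardised
  log rate with an independent Gaussian field at correlation `rho_c`
  (default 0.6), keeping each chromosome's own log-location and applying
  a single global rescale to a 2 cM/Mb mean — so `rho_c = 1` is exactly
  rank-preserving genome-wide.

Everything is driven by one integer seed through `SeedSequence`
spawning: identical config + seed give byte-identical files. What the
generator does *not* emulate: sequence evolution (no mutation spectra or
codon structure), LD itself (rates are the truth, not inferred),
assembly artefacts, and chromosome-scale synteny differences between the
sister species. Passing recovery tests therefore demonstrates that the
*analysis* chain is correct and calibrated, not that any particular
empirical claim about real genomes is reproduced.

## Problem sizes and calibration checks

The simulation-based checks run ten replicate studies at the default
~114 Mb genome, which keeps the whole suite and the acceptance script in
the low minutes on one core while leaving hundreds of 200 kb windows and
~900 promoters per replicate. Null calibrations (tau type-I error at
n = 200 over 2000 replicates; RT-contrast p-values with the coupling
switched off over the replicate seeds) are asserted as bands or KS
uniformity at alpha = 0.01; note a 2000-replicate rejection-rate
estimate carries a Monte Carlo standard error of ~0.005, so individual
estimates scatter around the true level accordingly.

## Known limitations

* The per-individual callable floor in `pi_windows` is approximate
  without an all-sites mask (see above).
* The complexity proxy ignores reverse-complement identity: a sequence
  and its reverse complement count as distinct k-mers, as in the
  forward-strand convention.
* Partial Kendall p-values use the asymptotic z transform; no
  permutation alternative is provided, and no spatial autocorrelation
  correction is attempted (windows are not independent — p-values for
  windowed correlations should be read as descriptive, which is also
  how the contrasts they mirror are usually reported).
* `DemographyModel.time_averaged_ne` needs a horizon for the open-ended
  last epoch; the default (last breakpoint plus the mean closed-epoch
  span) is a convention, and rho computed through `theta` is preferred.
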