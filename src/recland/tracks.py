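"""Sequence- and variant-derived per-window tracks.

Three tracks back the landscape analyses:

* **GC content** — (G+C)/(A+C+G+T) per window, ambiguity codes excluded
  from the denominator.
* **Nucleotide diversity (pi)** — windowed average pairwise difference from
  biallelic SNP genotypes, with unbiased per-site heterozygosity
  ``2*p*(1-p)*n/(n-1)`` and the missingness floors used for windowed
  popgen scans (minimum callable bp per window, minimum fraction of
  individuals meeting a per-window callable floor).
* **Sequence complexity (Cx)** — a [0, 1] genome-uniqueness proxy: the
  fraction of window positions whose forward k-mer occurs exactly once in
  the whole genome.  1 means fully unique sequence, 0 a perfect repeat.

Sequences are handled as numpy uint8 code arrays (A,C,G,T -> 0..3,
anything else -> 4) so whole chromosomes stay cheap to scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lower case


class TrackError(ValueError):
    pass


def encode_sequence(seq) -> np.ndarray:
    """Encode a DNA string/bytes (or pass through a uint8 code array)."""
    if isinstance(seq, np.ndarray) and seq.dtype == np.uint8:
        return seq
    if not isinstance(seq, (bytes, bytearray)):
        seq = str(seq).encode()
    return _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(b"ACGTN", dtype=np.uint8)[codes]).decode()


def _as_genome(genome) -> dict:
    """Normalise a genome argument to {chrom: uint8 codes}.

    Accepts a dict of strings/arrays or any mapping with string-like values
    (e.g. a pyfaidx.Fasta).
    """
    out = {}
    for chrom in list(genome.keys()) if hasattr(genome, "keys") else genome:
        out[str(chrom)] = encode_sequence(
            genome[chrom][:] if not isinstance(genome[chrom], (str, bytes, np.ndarray))
            else genome[chrom]
        )
    return out


def range_sums(values: np.ndarray, starts: np.ndarray,
               ends: np.ndarray) -> np.ndarray:
    """Sums of ``values`` over many half-open ranges, in O(len + n log n).

    Builds one segmented reduction over the union of range boundaries, so
    it stays fast even for boolean masks over whole chromosomes.
    """
    n = values.size
    starts = np.clip(np.asarray(starts, dtype=np.int64), 0, n)
    ends = np.clip(np.asarray(ends, dtype=np.int64), 0, n)
    if n == 0 or starts.size == 0:
        return np.zeros(starts.size)
    edges = np.unique(np.concatenate([starts, ends, [0, n]]))
    seg = np.add.reduceat(values, edges[:-1])
    # reduceat yields values[edges[i]] when edges[i] == edges[i+1]; zero those
    empty = np.diff(edges) == 0
    if empty.any():
        seg = np.where(empty, 0, seg)
    cum = np.concatenate([[0], np.cumsum(seg)])
    pos = np.searchsorted(edges, np.stack([starts, ends]))
    return cum[pos[1]] - cum[pos[0]]


# ------------------------------------------------------------------- GC
def gc_content_windows(genome, windows: pd.DataFrame) -> np.ndarray:
    """Per-window GC fraction; NaN where no unambiguous base exists."""
    seqs = _as_genome(genome)
    out = np.full(len(windows), np.nan)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        codes = seqs.get(str(chrom))
        if codes is None or codes.size == 0:
            continue
        s = wsub["start"].to_numpy()
        e = wsub["end"].to_numpy()
        gc = range_sums((codes == 1) | (codes == 2), s, e)
        denom = range_sums(codes < 4, s, e)
        with np.errstate(invalid="ignore"):
            out[wsub.index] = np.where(denom > 0, gc / np.maximum(denom, 1), np.nan)
    return out


# ------------------------------------------------------------------- pi
@dataclass
class SiteTable:
    """Biallelic SNP genotypes for one cohort, organised per chromosome.

    ``positions[chrom]`` is a sorted int64 array of 0-based SNP positions and
    ``genotypes[chrom]`` an (n_sites, n_samples) int8 matrix of alternate
    allele dosages (0, 1, 2) with 3 meaning a missing diploid genotype.
    """

    positions: dict
    genotypes: dict
    samples: list

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @classmethod
    def from_vcf(cls, path) -> "SiteTable":
        """Read biallelic SNP records from a VCF (plain or bgzipped)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        positions, genotypes = {}, {}
        pos_buf, gt_buf, cur = [], [], None

        def flush():
            if cur is not None and pos_buf:
                positions[cur] = np.asarray(pos_buf, dtype=np.int64)
                genotypes[cur] = np.asarray(gt_buf, dtype=np.int8)

        for v in vcf:
            if len(v.ALT) != 1 or not v.is_snp:
                continue
            if v.CHROM != cur:
                flush()
                cur, pos_buf, gt_buf = v.CHROM, [], []
            pos_buf.append(v.POS - 1)
            gt_buf.append(v.gt_types.copy())
        flush()
        if not positions:
            raise TrackError(f"{path}: no biallelic SNP genotypes found")
        return cls(positions, genotypes, list(vcf.samples))


def _mask_cum(mask: np.ndarray | None, length: int):
    """Cumulative callable-bp function from a (n,2) interval array."""
    if mask is None:
        mask = np.array([[0, length]], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(mask[:, 1] - mask[:, 0])])

    def before(x):
        idx = np.searchsorted(mask[:, 0], x, side="right") - 1
        ic = np.clip(idx, 0, None)
        inside = np.clip(x - mask[ic, 0], 0, mask[ic, 1] - mask[ic, 0])
        return np.where(idx < 0, 0, cum[ic] + inside)

    return before


def pi_windows(sites: SiteTable, windows: pd.DataFrame,
               callable_mask: dict | None = None,
               min_called_bp: int = 20_000,
               min_data_fraction: float = 0.7) -> np.ndarray:
    """Windowed nucleotide diversity from biallelic SNP genotypes.

    pi(window) = sum over SNPs of ``2*p*(1-p) * n/(n-1)`` divided by the
    callable bp of the window, with ``p`` the alternate-allele frequency and
    ``n`` the number of non-missing alleles at the site.  Monomorphic
    callable sites contribute zero, so the denominator is the callable
    length, not the SNP count.

    A window is missing (NaN) when its callable bp fall below
    ``min_called_bp``, or when fewer than ``min_data_fraction`` of the
    individuals reach the per-window callable floor.  Without an
    all-sites per-individual mask, an individual's callable bp in a window
    is approximated as callable bp times its non-missing genotype fraction
    at the window's SNPs (individuals with no SNPs in the window count as
    fully called).

    ``callable_mask`` maps chromosome to an (n, 2) half-open interval array;
    ``None`` means every position is callable (logged once).
    """
    if callable_mask is None:
        logger.warning("pi_windows: no callable mask; treating all positions "
                       "of each window as callable")
    out = np.full(len(windows), np.nan)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        chrom = str(chrom)
        pos = sites.positions.get(chrom)
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        before = _mask_cum(None if callable_mask is None
                           else callable_mask.get(chrom), int(we.max()))
        callable_bp = (before(we) - before(ws)).astype(float)
        if pos is None:
            vals = np.where(callable_bp >= min_called_bp, 0.0, np.nan)
            out[wsub.index] = vals
            continue
        gt = sites.genotypes[chrom]
        missing = gt == 3
        n_alleles = 2.0 * (gt.shape[1] - missing.sum(axis=1))
        alt = np.where(missing, 0, gt).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
            het = np.where(
                n_alleles > 1,
                2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1.0, 1.0),
                0.0,
            )
        # assign each SNP to its window (windows are sorted, non-overlapping)
        widx = np.searchsorted(ws, pos, side="right") - 1
        ok = (widx >= 0) & (pos < we[np.clip(widx, 0, None)])
        nw = len(wsub)
        het_sum = np.bincount(widx[ok], weights=het[ok], minlength=nw)
        # per-individual data fraction at this window's SNPs
        called_frac = np.ones((nw, gt.shape[1]))
        snp_count = np.bincount(widx[ok], minlength=nw).astype(float)
        miss_count = np.zeros((nw, gt.shape[1]))
        np.add.at(miss_count, widx[ok], missing[ok].astype(float))
        has_snps = snp_count > 0
        called_frac[has_snps] = 1.0 - miss_count[has_snps] / snp_count[has_snps, None]
        ind_callable = called_frac * callable_bp[:, None]
        frac_ok = (ind_callable >= min_called_bp).mean(axis=1)
        with np.errstate(invalid="ignore"):
            vals = het_sum / callable_bp
        vals[(callable_bp < min_called_bp) | (frac_ok < min_data_fraction)] = np.nan
        out[wsub.index] = vals
    return out


# ------------------------------------------------------------- complexity
def unique_kmer_index(genome, k: int = 16) -> dict:
    """Flag, per position, whether its forward k-mer is genome-unique.

    Returns ``{chrom: (unique, defined)}`` — boolean arrays over positions
    ``0 .. len-k``; ``defined`` is False where the k-mer window touches an
    ambiguous base.  Uniqueness is assessed jointly across all chromosomes.
    """
    if k < 8:
        raise TrackError("k must be >= 8")
    if k > 32:
        raise TrackError("k must be <= 32 (64-bit packing)")
    seqs = _as_genome(genome)
    codes_list, defined_list = {}, {}
    all_codes = []
    for chrom, codes in seqs.items():
        n = codes.size
        if n < k:
            codes_list[chrom] = np.empty(0, dtype=np.uint64)
            defined_list[chrom] = np.empty(0, dtype=bool)
            continue
        m = n - k + 1
        packed = np.zeros(m, dtype=np.uint64)
        base = np.where(codes < 4, codes, 0).astype(np.uint64)
        for j in range(k):
            packed = (packed << np.uint64(2)) | base[j:j + m]
        bad = np.cumsum(np.concatenate([[0], (codes >= 4).astype(np.int64)]))
        defined = (bad[k:] - bad[:-k]) == 0
        codes_list[chrom] = packed
        defined_list[chrom] = defined
        all_codes.append(packed[defined])
    if all_codes:
        pool = np.concatenate(all_codes)
        uniq, counts = np.unique(pool, return_counts=True)
        once = uniq[counts == 1]
    else:
        once = np.empty(0, dtype=np.uint64)
    out = {}
    for chrom in seqs:
        packed, defined = codes_list[chrom], defined_list[chrom]
        flags = np.zeros(packed.size, dtype=bool)
        if packed.size and once.size:
            hit = np.clip(np.searchsorted(once, packed), 0, once.size - 1)
            flags = defined & (once[hit] == packed)
        out[chrom] = (flags, defined)
    return out


def complexity_windows(flags: dict, windows: pd.DataFrame) -> np.ndarray:
    """Cx proxy per window: unique-k-mer positions / defined-k-mer positions.

    NaN where a window holds no defined k-mer start.  1 means every k-mer in
    the window is genome-unique; 0 means all are repeated.
    """
    out = np.full(len(windows), np.nan)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        entry = flags.get(str(chrom))
        if entry is None:
            continue
        uniq, defined = entry
        if uniq.size == 0:
            continue
        s = wsub["start"].to_numpy()
        e = wsub["end"].to_numpy()
        nu = range_sums(uniq, s, e)
        nd = range_sums(defined, s, e)
        with np.errstate(invalid="ignore"):
            out[wsub.index] = np.where(nd > 0, nu / np.maximum(nd, 1), np.nan)
    return out


def read_fasta(path) -> dict:
    """Read a FASTA into {name: uint8 code array} (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: encode_sequence(str(fa[name][:])) for name in fa.keys()}


def write_fasta(genome: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            if isinstance(seq, np.ndarray):
                seq = decode_sequence(seq)
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
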