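"""Strand-aware genomic feature sets and interval algebra.

Features live in a flat pandas table (chrom, start, end, strand, category,
id) with 0-based half-open coordinates.  GFF3 input (1-based inclusive) is
normalised on ingest; BED is taken as-is.  Category labels come from a
controlled vocabulary covering the annotation classes used in the
recombination-landscape analyses (genes, exons, UTRs, TSS, promoters with
and without CpG islands, intergenic space, and the three retrotransposon
families LTR / LINE / SINE).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = {
    "gene", "mRNA", "exon", "five_prime_UTR", "three_prime_UTR", "TSS",
    "promoter", "promoter_with_CpGi", "promoter_without_CpGi", "CpGi",
    "intergenic", "LTR", "LINE", "SINE",
}

_GFF_TYPE_MAP = {
    "gene": "gene",
    "mrna": "mRNA",
    "transcript": "mRNA",
    "exon": "exon",
    "five_prime_utr": "five_prime_UTR",
    "5'utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "3'utr": "three_prime_UTR",
}

COLUMNS = ["chrom", "start", "end", "strand", "category", "id"]


class FeatureError(ValueError):
    pass


class FeatureSet:
    """A sorted collection of labelled genomic intervals.

    Overlap within a category is permitted (transcript isoforms etc.) and is
    resolved per operation (union for coverage, counts for density).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col, default in (("strand", "+"), ("category", "feature"), ("id", None)):
            if col not in df.columns:
                df[col] = default
        df = df[COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if validate and len(df):
            bad = df[df["end"] <= df["start"]]
            if len(bad):
                row = bad.iloc[0]
                raise FeatureError(
                    f"feature with end <= start: {row['chrom']}:"
                    f"{row['start']}-{row['end']}"
                )
            unk = ~df["strand"].isin(["+", "-"])
            if unk.any():
                logger.warning(
                    "%d features with unknown strand treated as '+'", unk.sum()
                )
                df.loc[unk, "strand"] = "+"
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort",
                                 ignore_index=True)

    # ------------------------------------------------------------- basics
    def __len__(self):
        return len(self.df)

    def __repr__(self):
        cats = sorted(self.df["category"].unique())
        return f"FeatureSet({len(self)} features, categories={cats})"

    @classmethod
    def from_arrays(cls, chrom, starts, ends, strand="+", category="feature",
                    ids=None):
        n = len(starts)
        return cls(pd.DataFrame({
            "chrom": chrom if not np.isscalar(chrom) else [chrom] * n,
            "start": starts, "end": ends,
            "strand": strand if not np.isscalar(strand) else [strand] * n,
            "category": category if not np.isscalar(category) else [category] * n,
            "id": ids if ids is not None else [None] * n,
        }))

    def select(self, category) -> "FeatureSet":
        cats = {category} if isinstance(category, str) else set(category)
        return FeatureSet(self.df[self.df["category"].isin(cats)], validate=False)

    def by_chrom(self):
        return self.df.groupby("chrom", sort=True)

    def concat(self, other: "FeatureSet") -> "FeatureSet":
        return FeatureSet(pd.concat([self.df, other.df], ignore_index=True),
                          validate=False)

    def merged_intervals(self, chrom) -> np.ndarray:
        """Union of this set's intervals on one chromosome: (n, 2) array."""
        sub = self.df[self.df["chrom"] == chrom]
        return merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())

    def write_bed(self, path):
        out = self.df.copy()
        out["name"] = out["id"].fillna(out["category"])
        out["score"] = 0
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def merge_intervals(starts, ends) -> np.ndarray:
    """Merge possibly-overlapping intervals into a disjoint sorted union."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e[i])
        else:
            keep_s.append(s[i])
            keep_e.append(e[i])
    return np.column_stack([keep_s, keep_e]).astype(np.int64)


# ---------------------------------------------------------------------- IO
def read_features(path, category: str | None = None) -> FeatureSet:
    """Read GFF3 (1-based inclusive) or BED (0-based half-open).

    The format is sniffed from the extension and content.  GFF3 type columns
    are mapped onto the controlled vocabulary where possible; unmapped types
    keep their own label.  ``category`` overrides the label for BED input.
    """
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz"))
    if not is_gff and not path.endswith((".bed", ".bed.gz")):
        with open(path) as fh:
            first = fh.readline()
        is_gff = first.startswith("##gff") or len(first.split("\t")) == 9
    if is_gff:
        return _read_gff3(path)
    return _read_bed(path, category)


def _parse_gff_id(attr: str):
    for part in attr.split(";"):
        if part.startswith("ID="):
            return part[3:]
    return None


def _read_gff3(path) -> FeatureSet:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    if (df["end"] < df["start"]).any():
        raise FeatureError(f"{path}: GFF3 row with end < start")
    cat = df["type"].str.lower().map(_GFF_TYPE_MAP).fillna(df["type"])
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,       # 1-based inclusive -> half-open
        "end": df["end"],
        "strand": df["strand"].where(df["strand"].isin(["+", "-"]), "+"),
        "category": cat,
        "id": df["attributes"].map(_parse_gff_id),
    })
    return FeatureSet(out)


def _read_bed(path, category=None) -> FeatureSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    ncol = df.shape[1]
    out = pd.DataFrame({
        "chrom": df[0],
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
        "strand": df[5] if ncol > 5 else "+",
        "category": category if category is not None
        else (df[3] if ncol > 3 else "feature"),
        "id": df[3] if ncol > 3 else None,
    })
    if (out["end"] <= out["start"]).any():
        raise FeatureError(f"{path}: BED row with end <= start")
    return FeatureSet(out)


# ------------------------------------------------------------- derivations
def derive_tss(mrnas: FeatureSet) -> FeatureSet:
    """One 1-bp TSS per mRNA: the strand-aware first transcribed base.

    Identical (chrom, position, strand) TSS from isoforms sharing a start are
    collapsed to one.
    """
    df = mrnas.df
    plus = df["strand"] != "-"
    pos = np.where(plus, df["start"], df["end"] - 1)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": pos, "end": pos + 1,
        "strand": df["strand"], "category": "TSS", "id": df["id"],
    })
    out = out.drop_duplicates(subset=["chrom", "start", "strand"])
    return FeatureSet(out, validate=False)


def derive_promoters(tss: FeatureSet, length: int = 2000,
                     cpgi: FeatureSet | None = None,
                     chrom_lengths: dict | None = None) -> FeatureSet:
    """Promoters: the ``length`` bp immediately upstream of each TSS.

    ``[tss-length, tss)`` on '+', ``[tss+1, tss+1+length)`` on '-', clipped to
    chromosome bounds.  When ``cpgi`` is given, promoters are split into
    ``promoter_with_CpGi`` / ``promoter_without_CpGi`` by >= 1 bp overlap.
    """
    df = tss.df
    plus = df["strand"] != "-"
    start = np.where(plus, df["start"] - length, df["start"] + 1)
    end = np.where(plus, df["start"], df["start"] + 1 + length)
    start = np.maximum(start, 0)
    if chrom_lengths:
        lim = df["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, lim)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": start, "end": end,
        "strand": df["strand"], "category": "promoter", "id": df["id"],
    })
    out = out[out["end"] > out["start"]]
    proms = FeatureSet(out, validate=False)
    if cpgi is not None:
        with_i, without = overlap_split(proms, cpgi)
        wdf = with_i.df.assign(category="promoter_with_CpGi")
        odf = without.df.assign(category="promoter_without_CpGi")
        proms = FeatureSet(pd.concat([wdf, odf], ignore_index=True),
                           validate=False)
    return proms


def derive_intergenic(genes: FeatureSet, chrom_lengths: dict) -> FeatureSet:
    """Complement of the union of gene spans within each chromosome."""
    rows = []
    gene_df = genes.df
    for chrom, L in chrom_lengths.items():
        sub = gene_df[gene_df["chrom"] == chrom]
        merged = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        merged = np.clip(merged, 0, L)
        edges = np.concatenate([[0], merged.ravel(), [L]])
        for s, e in zip(edges[::2], edges[1::2]):
            if e > s:
                rows.append((chrom, s, e))
    if not rows:
        return FeatureSet(pd.DataFrame(columns=COLUMNS), validate=False)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["strand"], out["category"], out["id"] = "+", "intergenic", None
    return FeatureSet(out, validate=False)


def derive_non_exonic(exons: FeatureSet, chrom_lengths: dict) -> FeatureSet:
    """Complement of exon spans (an 'intergenic including introns' variant)."""
    fs = derive_intergenic(exons, chrom_lengths)
    fs.df["category"] = "non_exonic"
    return fs


# --------------------------------------------------------- window statistics
def window_density_coverage(features: FeatureSet, windows: pd.DataFrame,
                            mode: str = "coverage") -> np.ndarray:
    """Per-window feature density or coverage (bedtools-annotate semantics).

    density
        Count of features overlapping each window; a feature spanning k
        windows contributes once to each of the k.
    coverage
        Fraction of window bases covered by the union of the features.

    ``windows`` must hold sorted non-overlapping windows per chromosome.
    """
    if mode not in ("density", "coverage"):
        raise FeatureError(f"unknown mode {mode!r}")
    out = np.zeros(len(windows), dtype=float)
    widx = np.arange(len(windows))
    for chrom, wsub in windows.groupby("chrom", sort=False):
        fsub = features.df[features.df["chrom"] == chrom]
        if not len(fsub):
            continue
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        rows = widx[windows["chrom"] == chrom]
        if mode == "density":
            fs_ = fsub["start"].to_numpy()
            fe_ = fsub["end"].to_numpy()
            # first overlapped window: first window with end > feature start
            i0 = np.searchsorted(we, fs_, side="right")
            # last overlapped window: last window with start < feature end
            i1 = np.searchsorted(ws, fe_, side="left") - 1
            valid = i1 >= i0
            diff = np.zeros(len(wsub) + 1)
            np.add.at(diff, i0[valid], 1)
            np.add.at(diff, i1[valid] + 1, -1)
            out[rows] = np.cumsum(diff[:-1])
        else:
            merged = merge_intervals(fsub["start"].to_numpy(),
                                     fsub["end"].to_numpy())
            cum = np.concatenate([[0], np.cumsum(merged[:, 1] - merged[:, 0])])

            def cov_before(x):
                idx = np.searchsorted(merged[:, 0], x, side="right") - 1
                ic = np.clip(idx, 0, None)
                inside = np.clip(x - merged[ic, 0], 0,
                                 merged[ic, 1] - merged[ic, 0])
                return np.where(idx < 0, 0, cum[ic] + inside)

            covered = cov_before(we) - cov_before(ws)
            out[rows] = covered / (we - ws)
    return out


def mean_rate_by_feature(maps: dict, features: FeatureSet,
                         cM_per_Mb: bool = True):
    """Length-weighted mean map rate over each feature, and per-category
    aggregates.

    Features falling entirely in map gaps get NaN and are excluded from the
    per-category collections (used downstream for rank tests).

    Returns
    -------
    per_feature : DataFrame with a ``rate`` column aligned to ``features.df``
    per_category : DataFrame with n, mean and median per category
    """
    df = features.df
    rate = np.full(len(df), np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in maps:
            continue
        means, _ = maps[chrom].region_means(sub["start"].to_numpy(),
                                            sub["end"].to_numpy())
        rate[sub.index] = means
    if cM_per_Mb:
        rate = rate * 1e8
    per_feature = df.assign(rate=rate)
    grp = per_feature.dropna(subset=["rate"]).groupby("category")["rate"]
    per_category = grp.agg(n="count", mean="mean", median="median").reset_index()
    return per_feature, per_category


def overlap_mask(features: FeatureSet, others: FeatureSet,
                 family: str | None = None) -> np.ndarray:
    """Boolean mask over ``features.df`` rows: >= 1 bp overlap with
    ``others`` (optionally restricted to one category)."""
    if family is not None:
        others = others.select(family)
    mask = np.zeros(len(features.df), dtype=bool)
    for chrom, sub in features.df.groupby("chrom", sort=False):
        merged = others.merged_intervals(chrom)
        if merged.size == 0:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # overlap iff some merged interval has start < e and end > s;
        # merged intervals are disjoint + sorted, so ends are sorted too
        idx = np.searchsorted(merged[:, 0], e, side="left") - 1
        ic = np.clip(idx, 0, None)
        mask[sub.index] = (idx >= 0) & (merged[ic, 1] > s)
    return mask


def overlap_split(features: FeatureSet, others: FeatureSet,
                  family: str | None = None):
    """Partition ``features`` by >= 1 bp overlap with ``others``.

    ``family`` optionally restricts ``others`` to one category first.
    Returns ``(overlapping, non_overlapping)``; the two parts are disjoint
    and jointly exhaustive.
    """
    mask = overlap_mask(features, others, family)
    return (FeatureSet(features.df[mask], validate=False),
            FeatureSet(features.df[~mask], validate=False))


def tile_windows(chrom_lengths: dict, window_size: int) -> pd.DataFrame:
    """Non-overlapping windows tiled from 0; last partial window kept."""
    frames = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, int(L), window_size, dtype=np.int64)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + window_size, int(L)),
        }))
    return pd.concat(frames, ignore_index=True)
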