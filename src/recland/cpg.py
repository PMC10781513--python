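"""Distance-based CpG-island detection.

CpG islands are found by clustering CpG dinucleotides whose spacings are
anomalously small relative to the chromosome-wide spacing distribution:

1. record the position of every CG dinucleotide (the C, 0-based);
2. set the clustering threshold to the (integer-floored) median of
   consecutive CpG distances on the chromosome;
3. a candidate island is a maximal run of >= 2 CpGs whose consecutive
   distances are all <= threshold, spanning first C to last G;
4. significance: under the null CpGs form a stationary point process with
   per-position rate ``p = n_cpg / sequence_length`` (the reciprocal of
   the mean inter-CpG distance were CpGs homogeneously scattered), so
   spacings are i.i.d. geometric and the total intra-island distance
   ``D`` (a sum of ``n_cpg - 1`` spacings, each >= 1) follows a shifted
   negative binomial; the island p-value is ``P(D' <= D)`` under that
   null;
5. retain islands with length >= ``min_length`` and p <= ``max_p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureSet
from .tracks import encode_sequence


@dataclass(frozen=True)
class CpGIsland:
    chromosome: str
    start: int          # first CpG's C
    end: int            # last CpG's G + 1 (half-open)
    n_cpg: int
    p_value: float

    @property
    def length(self) -> int:
        return self.end - self.start


def cpg_positions(sequence) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (overlap scan,
    case-insensitive)."""
    codes = encode_sequence(sequence)
    if codes.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2)).astype(np.int64)


def distance_threshold(positions: np.ndarray) -> int | None:
    """Integer-floored median of consecutive CpG distances; None if < 2 CpGs."""
    positions = np.asarray(positions)
    if positions.size < 2:
        return None
    return int(np.floor(np.median(np.diff(positions))))


def _island_pvalues(d_sums: np.ndarray, n_cpgs: np.ndarray, p_hat: float):
    """P(total distance <= D) for runs of n_cpg CpGs under geometric spacing.

    Each spacing is 1 + Geometric(p_hat) failures, so the total over
    ``n_cpg - 1`` spacings minus that count follows NB(n_cpg - 1, p_hat).
    """
    k = n_cpgs - 1
    return stats.nbinom.cdf(d_sums - k, k, p_hat)


def detect_islands(sequence, chromosome: str = "chr",
                   min_length: int = 50, max_p: float = 1e-5,
                   threshold: int | None = None) -> list[CpGIsland]:
    """Detect CpG islands on one sequence.

    ``threshold`` overrides the per-chromosome median distance (useful when a
    genome-wide threshold is preferred).  Returns retained islands only,
    sorted by start.
    """
    codes = encode_sequence(sequence)
    pos = cpg_positions(codes)
    if pos.size < 2:
        return []
    dist = np.diff(pos)
    if threshold is None:
        threshold = distance_threshold(pos)
    # null rate: CpG starts per position over the whole sequence, so local
    # clusters are judged against the homogeneous background, not against
    # themselves
    p_hat = min(pos.size / float(codes.size), 0.5)
    close = dist <= threshold
    if not close.any():
        return []
    # maximal runs of consecutive close spacings
    edges = np.diff(np.concatenate([[0], close.astype(np.int8), [0]]))
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)      # exclusive, in spacing index
    n_cpgs = (run_ends - run_starts) + 1
    d_cum = np.concatenate([[0], np.cumsum(dist)])
    d_sums = d_cum[run_ends] - d_cum[run_starts]
    starts = pos[run_starts]
    ends = pos[run_ends] + 2                     # last CpG's G, half-open
    pvals = _island_pvalues(d_sums, n_cpgs, p_hat)
    keep = ((ends - starts) >= min_length) & (pvals <= max_p)
    return [
        CpGIsland(chromosome, int(s), int(e), int(n), float(p))
        for s, e, n, p in zip(starts[keep], ends[keep], n_cpgs[keep], pvals[keep])
    ]


def detect_islands_genome(genome: dict, min_length: int = 50,
                          max_p: float = 1e-5) -> FeatureSet:
    """Per-chromosome island detection over a genome; returns a FeatureSet
    with category ``CpGi``."""
    rows = []
    for chrom, seq in genome.items():
        for isl in detect_islands(seq, chrom, min_length, max_p):
            rows.append((isl.chromosome, isl.start, isl.end, isl.n_cpg,
                         isl.p_value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg", "p"])
    return FeatureSet(pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "strand": "+", "category": "CpGi",
        "id": [f"CpGi_{i}" for i in range(len(df))],
    }), validate=False) if len(df) else FeatureSet(
        pd.DataFrame(columns=["chrom", "start", "end", "strand", "category", "id"]),
        validate=False,
    )


def islands_to_bed(islands: list[CpGIsland], path) -> None:
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chromosome}\t{isl.start}\t{isl.end}\t"
                     f"{isl.n_cpg}\t{isl.p_value:.3g}\n")
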