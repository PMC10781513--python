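"""Piecewise-constant recombination maps and their unit calculus.

An LD-based recombination map assigns a per-base-pair, per-generation
crossover rate ``r`` to a set of sorted, non-overlapping, half-open
genomic intervals.  Gaps between intervals mean "no estimate" — they are
treated as missing data throughout, never as rate zero, because LD-based
estimators only emit rates between informative SNP pairs and zero-filling
would bias every windowed average downward.

Unit conventions
----------------
* ``r``   — crossovers / bp / generation (1e-8 corresponds to 1 cM/Mb).
* cM      — centiMorgans; map length of a region = 100 x sum(r_i * len_i).
* rho     — population-scaled rate, 4 * Ne * r.

All coordinates are 0-based half-open; readers can convert 1-based input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Chromosomes shorter than this many bp are classed as microchromosomes.
MICRO_THRESHOLD = 20_000_000

#: Default per-bp per-generation mutation rate (collared flycatcher estimate,
#: commonly borrowed for songbirds lacking a direct pedigree estimate).
DEFAULT_MU = 4.6e-9


class RateMapError(ValueError):
    """Raised for invalid map structure or invalid queries."""


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative genetic map: positions (bp) and cumulative distance (cM)."""

    chromosome: str
    positions: np.ndarray
    cM: np.ndarray

    @property
    def total_cM(self) -> float:
        return float(self.cM[-1]) if self.cM.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chromosome, "pos": self.positions, "cM": self.cM}
        )


class RateMap:
    """A per-chromosome piecewise-constant recombination rate map.

    Parameters
    ----------
    chromosome
        Chromosome identifier.
    starts, ends
        Interval bounds, 0-based half-open, sorted and non-overlapping.
    rates
        Per-bp per-generation rate for each interval; finite and >= 0.
    """

    def __init__(self, chromosome, starts, ends, rates, validate=True):
        self.chromosome = str(chromosome)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.rates = np.asarray(rates, dtype=np.float64)
        if validate:
            self._validate()
        # Cumulative genetic mass (Morgans, i.e. sum r*len) and covered bp at
        # each interval start; used for O(log n) region queries.
        lens = self.ends - self.starts
        self._cummass = np.concatenate([[0.0], np.cumsum(self.rates * lens)])
        self._cumcov = np.concatenate([[0], np.cumsum(lens)])

    def _validate(self):
        s, e, r = self.starts, self.ends, self.rates
        if not (s.shape == e.shape == r.shape) or s.ndim != 1:
            raise RateMapError("starts/ends/rates must be 1-D and equal length")
        if s.size == 0:
            return
        bad = np.flatnonzero(e <= s)
        if bad.size:
            raise RateMapError(
                f"{self.chromosome}: interval {bad[0]} has end <= start "
                f"({s[bad[0]]}, {e[bad[0]]})"
            )
        bad = np.flatnonzero(s[1:] < e[:-1])
        if bad.size:
            i = bad[0]
            raise RateMapError(
                f"{self.chromosome}: intervals {i} and {i + 1} overlap or are "
                f"out of order ({s[i]}-{e[i]} then {s[i + 1]}-{e[i + 1]})"
            )
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise RateMapError(f"{self.chromosome}: rates must be finite and >= 0")

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return self.starts.size

    def __repr__(self) -> str:
        return (
            f"RateMap({self.chromosome!r}, {len(self)} intervals, "
            f"span={self.span}, {self.total_cM:.4g} cM)"
        )

    @property
    def span(self) -> int:
        """End coordinate of the last interval (0 for an empty map)."""
        return int(self.ends[-1]) if len(self) else 0

    @property
    def covered_bp(self) -> int:
        return int(self._cumcov[-1])

    @property
    def total_mass(self) -> float:
        """Total expected crossovers over the map (sum r_i * len_i), Morgans."""
        return float(self._cummass[-1])

    @property
    def total_cM(self) -> float:
        return 100.0 * self.total_mass

    def mean_rate(self) -> float:
        """Length-weighted mean r over covered bases (NaN for empty maps)."""
        if self.covered_bp == 0:
            return float("nan")
        return self.total_mass / self.covered_bp

    # --------------------------------------------------------------- queries
    def _mass_cov_before(self, x):
        """Vectorised (genetic mass, covered bp) accumulated over [0, x)."""
        x = np.asarray(x, dtype=np.int64)
        if len(self) == 0:
            return np.zeros(x.shape), np.zeros(x.shape, dtype=np.int64)
        idx = np.searchsorted(self.starts, x, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        inside = np.clip(x - self.starts[idx_c], 0, self.ends[idx_c] - self.starts[idx_c])
        inside = np.where(idx < 0, 0, inside)
        mass = self._cummass[idx_c] + self.rates[idx_c] * inside
        cov = self._cumcov[idx_c] + inside
        mass = np.where(idx < 0, 0.0, mass)
        cov = np.where(idx < 0, 0, cov)
        return mass, cov

    def region_means(self, starts, ends):
        """Length-weighted mean rate and covered bp for many regions at once.

        Returns ``(means, covered)``; ``means`` is NaN where no map interval
        overlaps the region (gap semantics: missing, not zero).
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise RateMapError("regions must satisfy start < end")
        m0, c0 = self._mass_cov_before(starts)
        m1, c1 = self._mass_cov_before(ends)
        cov = c1 - c0
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cov > 0, (m1 - m0) / np.maximum(cov, 1), np.nan)
        return means, cov

    def weighted_mean_rate(self, start: int, end: int):
        """Distance-weighted mean rate over ``[start, end)``.

        Returns ``(mean_r, covered_bp)``; ``mean_r`` is NaN when the region
        lies entirely in a gap.
        """
        means, cov = self.region_means([start], [end])
        return float(means[0]), int(cov[0])

    def cumulative_genetic_map(self) -> GeneticMap:
        """Cumulative cM at every interval boundary; gaps contribute 0 cM.

        The map starts at 0 cM at the first mapped position.
        """
        if len(self) == 0:
            return GeneticMap(self.chromosome, np.array([], dtype=np.int64),
                              np.array([], dtype=np.float64))
        # boundary positions: each interval start and end, deduplicated where
        # intervals abut.
        pos = np.unique(np.concatenate([self.starts, self.ends]))
        mass, _ = self._mass_cov_before(pos)
        return GeneticMap(self.chromosome, pos, 100.0 * mass)

    def window_rates(self, window_size: int, min_covered_fraction: float = 0.5,
                     chrom_length: int | None = None) -> pd.DataFrame:
        """Distance-weighted mean rates in non-overlapping windows from 0.

        The last partial window is retained with its true span.  Windows whose
        covered fraction falls below ``min_covered_fraction`` have ``rate``
        (and ``rate_cM_Mb``) set to NaN but keep their ``covered_bp``, so mass
        accounting stays auditable.
        """
        if window_size <= 0:
            raise RateMapError("window_size must be positive")
        L = int(chrom_length) if chrom_length is not None else self.span
        if L <= 0:
            return pd.DataFrame(
                columns=["chrom", "start", "end", "rate", "rate_cM_Mb",
                         "covered_bp", "covered_fraction"]
            )
        starts = np.arange(0, L, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, L)
        means, cov = self.region_means(starts, ends)
        frac = cov / (ends - starts)
        rate = np.where(frac >= min_covered_fraction, means, np.nan)
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": starts,
                "end": ends,
                "rate": rate,
                "rate_cM_Mb": rate * 1e8,
                "covered_bp": cov,
                "covered_fraction": frac,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chromosome, "start": self.starts, "end": self.ends,
             "rate": self.rates}
        )


# ----------------------------------------------------------------- unit calc
def rate_to_cM_per_Mb(r):
    """Convert a per-bp per-generation rate to cM/Mb (r * 1e8)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise RateMapError("rate must be >= 0")
    out = r * 1e8
    return float(out) if out.ndim == 0 else out


def cM_per_Mb_to_rate(c):
    """Inverse of :func:`rate_to_cM_per_Mb`."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise RateMapError("rate must be >= 0")
    out = c * 1e-8
    return float(out) if out.ndim == 0 else out


def effective_population_size(theta: float, mu: float = DEFAULT_MU,
                              factor: int = 4) -> float:
    """Ne from the population mutation parameter theta.

    ``factor=4`` uses the standard theta = 4*Ne*mu; ``factor=1`` reproduces
    the literal "theta divided by mutation rate" convention.
    """
    if theta <= 0 or mu <= 0:
        raise RateMapError("theta and mu must be positive")
    if factor not in (1, 4):
        raise RateMapError("factor must be 1 or 4")
    return theta / (factor * mu)


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant Ne trajectory over generation-time breakpoints."""

    times: tuple = ()          # epoch start times in generations, increasing from 0
    ne: tuple = ()             # Ne per epoch, > 0
    mutation_rate: float = DEFAULT_MU

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.ne, dtype=float)
        if t.size != n.size:
            raise RateMapError("times and ne must have equal length")
        if t.size:
            if t[0] != 0 or np.any(np.diff(t) <= 0):
                raise RateMapError("epoch times must strictly increase from 0")
            if np.any(n <= 0):
                raise RateMapError("Ne must be positive")

    @classmethod
    def read(cls, path, mutation_rate: float = DEFAULT_MU) -> "DemographyModel":
        """Read a 2-column (generation, Ne) whitespace table."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["time", "ne"])
        return cls(tuple(df["time"]), tuple(df["ne"]), mutation_rate)

    def time_averaged_ne(self, horizon: float | None = None) -> float:
        """Duration-weighted mean Ne up to ``horizon`` generations.

        The open-ended last epoch is truncated at ``horizon`` (default: the
        last breakpoint plus the mean span of the closed epochs).
        """
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.ne, dtype=float)
        if t.size == 0:
            raise RateMapError("empty demography")
        if t.size == 1:
            return float(n[0])
        if horizon is None:
            horizon = t[-1] + np.mean(np.diff(t))
        edges = np.append(t, max(horizon, t[-1] + 1.0))
        w = np.diff(edges)
        return float(np.sum(w * n) / np.sum(w))


@dataclass(frozen=True)
class ChromosomeSummary:
    """Per-chromosome aggregate of an LD-based recombination map."""

    chromosome: str
    length_bp: int
    mean_r: float                 # length-weighted mean r over covered bases
    mean_rate_cM_Mb: float        # mean r expressed in cM/Mb
    map_length_cM: float          # 100 * sum(r_i * len_i)
    expected_crossovers: float    # mean r * chromosome length
    rho: float = field(default=float("nan"))   # 4 * Ne * mean r (per bp)
    size_class: str = "macro"

    def to_dict(self):
        return {
            "chrom": self.chromosome,
            "length_bp": self.length_bp,
            "mean_r": self.mean_r,
            "mean_rate_cM_Mb": self.mean_rate_cM_Mb,
            "map_length_cM": self.map_length_cM,
            "expected_crossovers": self.expected_crossovers,
            "rho": self.rho,
            "size_class": self.size_class,
        }


def chromosome_summary(rate_map: RateMap, length: int,
                       demography: DemographyModel | None = None,
                       theta: float | None = None,
                       mu: float | None = None,
                       ne_factor: int = 4,
                       micro_threshold: int = MICRO_THRESHOLD) -> ChromosomeSummary:
    """Summarise one chromosome's map: mean rate, map length, expected
    crossovers, rho, and macro/micro class.

    Ne for rho is derived from ``theta`` (theta / (factor * mu)) when given,
    otherwise from the demography's time-averaged Ne; rho is NaN when neither
    is available.
    """
    if length < rate_map.span:
        raise RateMapError(
            f"chromosome length {length} < map span {rate_map.span}"
        )
    mean_r = rate_map.mean_rate()
    mu_eff = mu if mu is not None else (
        demography.mutation_rate if demography is not None else DEFAULT_MU
    )
    rho = float("nan")
    if theta is not None:
        if theta <= 0:
            raise RateMapError("theta must be positive for rho")
        ne = effective_population_size(theta, mu_eff, ne_factor)
        rho = 4.0 * ne * mean_r
    elif demography is not None and len(demography.times):
        rho = 4.0 * demography.time_averaged_ne() * mean_r
    return ChromosomeSummary(
        chromosome=rate_map.chromosome,
        length_bp=int(length),
        mean_r=mean_r,
        mean_rate_cM_Mb=mean_r * 1e8,
        map_length_cM=rate_map.total_cM,
        expected_crossovers=mean_r * length,
        rho=rho,
        size_class="micro" if length < micro_threshold else "macro",
    )


def summarize_genome(maps: dict, chrom_lengths: dict, **kwargs) -> pd.DataFrame:
    """ChromosomeSummary table for a whole map collection."""
    rows = [
        chromosome_summary(maps[c], chrom_lengths[c], **kwargs).to_dict()
        for c in maps
    ]
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ IO
def read_rate_map(path, chromosome: str | None = None,
                  one_based: bool = False) -> dict:
    """Read a Pyrho-style whitespace rate-map text file.

    Two dialects are accepted: 3 columns (``start end rate``; requires
    ``chromosome``) and 4 columns (``chrom start end rate``).  Coordinates are
    0-based half-open unless ``one_based`` is set, in which case starts are
    shifted down by one on ingest.

    Returns a dict ``{chromosome: RateMap}``.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if ncols is None:
                ncols = len(parts)
                if ncols not in (3, 4):
                    raise RateMapError(
                        f"{path}:{lineno}: expected 3 or 4 columns, got {ncols}"
                    )
                if ncols == 3 and chromosome is None:
                    raise RateMapError(
                        "3-column map files need an explicit chromosome name"
                    )
            if len(parts) != ncols:
                raise RateMapError(
                    f"{path}:{lineno}: inconsistent column count"
                )
            try:
                if ncols == 3:
                    chrom = chromosome
                    s, e, r = parts
                else:
                    chrom, s, e, r = parts
                rows.append((chrom, int(float(s)), int(float(e)), float(r), lineno))
            except ValueError as exc:
                raise RateMapError(f"{path}:{lineno}: malformed row ({exc})")
    if not rows:
        logger.warning("rate map file %s is empty", path)
        return {}
    out = {}
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate", "lineno"])
    shift = 1 if one_based else 0
    for chrom, g in df.groupby("chrom", sort=False):
        bad = g.index[np.flatnonzero(np.diff(g["start"].to_numpy()) < 0)]
        if len(bad):
            raise RateMapError(
                f"{path}:{g.loc[bad[0] + 1, 'lineno']}: intervals out of order"
            )
        try:
            # 1-based inclusive -> 0-based half-open: shift starts down only.
            out[chrom] = RateMap(
                chrom, g["start"].to_numpy() - shift, g["end"].to_numpy(),
                g["rate"].to_numpy(),
            )
        except RateMapError as exc:
            raise RateMapError(f"{path}: {exc}")
    return out


def write_rate_map(maps: dict, path, with_chrom: bool = True) -> None:
    """Write a map collection in Pyrho-style text (4-column by default)."""
    with open(path, "w") as fh:
        for chrom in maps:
            m = maps[chrom]
            for s, e, r in zip(m.starts, m.ends, m.rates):
                if with_chrom:
                    fh.write(f"{chrom}\t{s}\t{e}\t{r:.10g}\n")
                else:
                    fh.write(f"{s}\t{e}\t{r:.10g}\n")


def write_bedgraph(df: pd.DataFrame, path, column: str = "rate_cM_Mb") -> None:
    """Write a window table column as BedGraph (chrom, start, end, value)."""
    sub = df[["chrom", "start", "end", column]].dropna(subset=[column])
    sub.to_csv(path, sep="\t", header=False, index=False)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", header=False, index=False)
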