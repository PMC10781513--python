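"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's interval algebra: they expand
maps to per-base arrays and loop, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recland.ratemap import RateMap


def random_rate_map(rng, span=10_000, max_intervals=30, gap_prob=0.3,
                    chrom="chr") -> RateMap:
    """A random valid map on [0, span) with gaps and varied interval sizes."""
    n_cuts = rng.integers(2, max_intervals)
    cuts = np.unique(rng.integers(0, span, size=n_cuts))
    cuts = np.concatenate([[0], cuts, [span]])
    cuts = np.unique(cuts)
    starts, ends, rates = [], [], []
    for s, e in zip(cuts[:-1], cuts[1:]):
        if rng.random() < gap_prob:
            continue  # leave a gap: "no estimate"
        starts.append(s)
        ends.append(e)
        rates.append(rng.uniform(0, 5e-8))
    if not starts:  # ensure non-empty
        starts, ends, rates = [0], [span], [rng.uniform(0, 5e-8)]
    return RateMap(chrom, starts, ends, rates)


def per_base_rates(rate_map: RateMap, length=None) -> np.ndarray:
    """Expand a map to a per-base rate array with NaN in gaps (oracle)."""
    L = length or rate_map.span
    arr = np.full(L, np.nan)
    for s, e, r in zip(rate_map.starts, rate_map.ends, rate_map.rates):
        arr[s:min(e, L)] = r
    return arr


def per_base_region_mean(rate_map: RateMap, start, end):
    """Brute-force weighted mean over a region via an explicit per-base loop."""
    arr = per_base_rates(rate_map, max(rate_map.span, end))
    seg = arr[start:end]
    seg = seg[np.isfinite(seg)]
    return (seg.mean(), seg.size) if seg.size else (np.nan, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_map():
    return RateMap("chr1", [0, 100], [100, 300], [1e-8, 3e-8])


@pytest.fixture
def small_windows():
    return pd.DataFrame({
        "chrom": "chr1",
        "start": [0, 1000, 2000],
        "end": [1000, 2000, 3000],
    })
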