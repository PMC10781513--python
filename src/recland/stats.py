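"""Rank-statistics kernel.

Recombination rates are roughly exponentially distributed along genomes,
so the association analyses use rank statistics throughout: Kendall's
tau-b (tie-corrected) for pairwise association, a partial Kendall matrix
(inverse-correlation formula, the ppcor convention) for confound-adjusted
association, Wilcoxon rank-sum (Mann-Whitney) for two-group contrasts,
Welch's t for class-mean contrasts, and Holm / Benjamini-Hochberg
multiplicity adjustment.

A convenient consequence of working on ranks: any strictly increasing
transform of a variable (log chromosome length, square-root rates) leaves
tau unchanged, so those transforms are presentation choices, not
modelling ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05  # conventional significance threshold used by the analyses


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    """A (partial) rank correlation with its two-sided p-value."""

    tau: float
    p_value: float
    n: int
    conditioned_on: tuple = field(default_factory=tuple)
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= ALPHA)


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b with the tie-corrected normal-approximation p-value.

    Missing values are removed pairwise.  Zero variance in either vector
    yields tau = NaN flagged via ``zero_variance``.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 2:
        raise StatsError("kendall_tau_b needs n >= 2 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(float("nan"), float("nan"), n,
                                 zero_variance=True)
    tau, p = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(float(tau), float(p), n)


def kendall_tau_b_brute(x, y):
    """O(n^2) enumeration of tau-b (independent oracle; no p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i, j in combinations(range(n), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else float("nan")


def partial_kendall(matrix, labels=None):
    """Partial Kendall correlation matrix (ppcor convention).

    Rows with any missing value are removed listwise.  The pairwise tau-b
    matrix ``T`` is inverted; ``partial_ij = -Om_ij / sqrt(Om_ii * Om_jj)``
    with ``Om = T^-1``.  Two-sided p-values use
    ``z = partial * sqrt(9 m (m-1) / (2 (2m + 5)))`` with ``m = n - (k - 2)``.

    Returns ``(partial, pvalues, n)`` as (k, k) arrays, or a dict of
    CorrelationResult keyed by label pairs when ``labels`` is given.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise StatsError("partial_kendall needs an n x k matrix with k >= 3")
    X = X[np.all(np.isfinite(X), axis=1)]
    n, k = X.shape
    if n <= k:
        raise StatsError(f"too few complete rows (n={n}) for k={k} variables")
    T = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            tau, _ = sps.kendalltau(X[:, i], X[:, j], variant="b",
                                    method="asymptotic")
            if not np.isfinite(tau):
                raise StatsError(
                    f"zero-variance column {i} or {j}; tau undefined"
                )
            T[i, j] = T[j, i] = tau
    try:
        om = np.linalg.inv(T)
    except np.linalg.LinAlgError:
        pair = _most_collinear(T)
        raise StatsError(f"singular tau matrix; columns {pair} are collinear")
    if not np.all(np.isfinite(om)) or np.linalg.cond(T) > 1e12:
        pair = _most_collinear(T)
        raise StatsError(f"singular tau matrix; columns {pair} are collinear")
    d = np.sqrt(np.diag(om))
    partial = -om / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    m = n - (k - 2)
    z = partial * np.sqrt(9.0 * m * (m - 1) / (2.0 * (2 * m + 5)))
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    np.fill_diagonal(pvals, 0.0)
    if labels is None:
        return partial, pvals, n
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            cond = tuple(l for h, l in enumerate(labels) if h not in (i, j))
            out[(labels[i], labels[j])] = CorrelationResult(
                float(partial[i, j]), float(pvals[i, j]), n, cond
            )
    return out


def _most_collinear(T):
    k = T.shape[0]
    off = np.abs(T - np.eye(k))
    i, j = np.unravel_index(np.argmax(off), off.shape)
    return (min(i, j), max(i, j))


def partial_kendall_k3(tau_xy, tau_xz, tau_yz):
    """Closed-form first-order partial correlation (k = 3 recursion)."""
    denom = np.sqrt((1 - tau_xz ** 2) * (1 - tau_yz ** 2))
    return (tau_xy - tau_xz * tau_yz) / denom


# ------------------------------------------------------------- rank-sum
def _exact_wilcoxon_p(ranks_a_sum, ranks, n_a):
    """Two-sided exact p by enumerating all assignments of midranks."""
    n = len(ranks)
    sums = np.array([sum(c) for c in combinations(ranks, n_a)])
    mean = sums.mean()
    obs_dev = abs(ranks_a_sum - mean)
    # two-sided: total probability of |deviation| >= observed (with a small
    # tolerance for float midranks)
    return float(np.mean(np.abs(sums - mean) >= obs_dev - 1e-9))


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12):
    """Unpaired two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks handle ties.  The p-value is exact (full enumeration over
    label assignments) when ``n_a + n_b <= exact_max_n``, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.

    Returns ``(U, p)`` where U counts pairs (a_i, b_j) with a_i > b_j
    (ties half-weighted).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(r_a, list(ranks), n_a)
        return float(u), float(p)
    mean_u = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1.0))
    var_u = n_a * n_b / 12.0 * ((n + 1.0) - tie_term)
    if var_u <= 0:
        return float(u), 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    return float(u), float(2.0 * sps.norm.sf(max(z, 0.0)))


def welch_t(a, b):
    """Welch's two-sample t-test (unequal variances); returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("welch_t needs n >= 2 in each sample")
    if np.var(a) == 0 and np.var(b) == 0:
        raise StatsError("degenerate (zero-variance) samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------- multiplicity
def holm_adjust(pvalues):
    """Step-down Holm adjustment (monotone, conservative FWER control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(pvalues):
    """Benjamini-Hochberg FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust(pvalues, method: str = "holm"):
    if method == "holm":
        return holm_adjust(pvalues)
    if method in ("bh", "fdr_bh"):
        return bh_adjust(pvalues)
    if method == "none":
        return np.asarray(pvalues, dtype=float)
    raise StatsError(f"unknown adjustment method {method!r}")
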