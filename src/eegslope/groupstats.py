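"""Nonparametric group comparisons, cluster correction, FDR and regression.

Implements the statistical machinery used on slope profiles and band
slopes: bootstrap standard error of the median, Wilcoxon rank-sum (exact
by dynamic-programming enumeration for small samples without ties, normal
approximation with tie correction otherwise), Kruskal-Wallis, run-length
cluster correction (>= 3 consecutive significant bins), Benjamini-Hochberg
FDR, ordinary least-squares slope-vs-age regression, case-control matching
(same gender, age within +-1 year, controls aggregated to a single point),
and R^2-distribution subsample matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "MatchedPairs",
    "GroupComparison",
    "bootstrap_median_sem",
    "rank_sum_test",
    "kruskal_wallis_test",
    "signed_rank_test",
    "cluster_significant",
    "bh_fdr",
    "regress_slope_vs_age",
    "pair_case_controls",
    "subsample_match_r2",
    "compare_groups",
]


# --------------------------------------------------------------------------
# Bootstrap SEM
# --------------------------------------------------------------------------


def bootstrap_median_sem(
    values: Sequence[float], n_iter: int = 10000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Median and its bootstrap standard error (SD of resampled medians).

    10,000 with-replacement resamples by default; deterministic per seed.
    Missing values are dropped; all-missing input returns (nan, nan).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan, np.nan
    if v.size < 2:
        return float(np.median(v)), np.nan
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    medians = np.median(v[idx], axis=1)
    return float(np.median(v)), float(np.std(medians, ddof=1))


# --------------------------------------------------------------------------
# Rank tests
# --------------------------------------------------------------------------


def _ranksum_distribution(n1: int, n_total: int) -> np.ndarray:
    """Counts of rank-sum values for subsets of size n1 from ranks 1..n_total.

    ``out[s]`` is the number of size-n1 subsets with rank sum s (index 0
    unused below the minimum).  Dynamic programming over items, O(n1 *
    n_total * S).
    """
    max_sum = n1 * n_total
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n1), 0, -1):
            table[k, rank:] += table[k - 1, : max_sum + 1 - rank]
    return table[n1]


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (DP over the rank-sum distribution) when the smaller
    group has <= ``exact_max_n`` observations and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    t_a = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and min(n1, n2) <= exact_max_n:
        dist = _ranksum_distribution(n1, n)
        total = dist.sum()
        mean = n1 * (n + 1) / 2.0
        dev = abs(t_a - mean)
        sums = np.arange(dist.size, dtype=float)
        p = dist[np.abs(sums - mean) >= dev - 1e-9].sum() / total
        return float(min(p, 1.0))

    mean = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    dev = abs(t_a - mean) - 0.5  # continuity correction
    z = max(dev, 0.0) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(z))


def kruskal_wallis_test(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis p-value (H with tie correction, chi^2 on k-1 df)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [g[np.isfinite(g)] for g in arrays]
    if len(arrays) < 2 or any(g.size < 1 for g in arrays):
        raise ValueError("need >= 2 groups with >= 1 value each")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction <= 0:
        return 1.0  # all observations identical
    h /= correction
    return float(sps.chi2.sf(h, len(arrays) - 1))


def signed_rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    return float(sps.wilcoxon(d, alternative="two-sided").pvalue)


# --------------------------------------------------------------------------
# Multiple-comparison handling
# --------------------------------------------------------------------------


def cluster_significant(
    p_values: Sequence[float], alpha: float, min_len: int = 3
) -> np.ndarray:
    """Mask of windows belonging to runs of >= ``min_len`` consecutive p < alpha.

    NaN p-values break runs.  The correction only restricts: the returned
    mask is a subset of plain ``p < alpha`` thresholding.
    """
    p = np.asarray(p_values, dtype=float)
    sig = np.zeros(p.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        below = (p < alpha) & np.isfinite(p)
    out = np.zeros_like(below)
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``alpha``.

    Rejects all p <= p_(k*) where k* = max{k : p_(k) <= k alpha / m}.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * alpha
    passing = np.nonzero(ranked <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    threshold = ranked[passing[-1]]
    return p <= threshold


# --------------------------------------------------------------------------
# Regression
# --------------------------------------------------------------------------


@dataclass
class RegressionResult:
    beta1: float  # intercept
    beta2: float  # slope per year
    r_squared: float
    p_value: float
    se_beta2: float
    n: int


def regress_slope_vs_age(
    ages: Sequence[float], slopes: Sequence[float]
) -> RegressionResult:
    """OLS of slope on age: y = beta1 + beta2 * x, p from the t statistic on beta2."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(slopes, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 points for regression")
    if np.var(x) == 0:
        raise ValueError("degenerate design: no age variance")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    beta2 = float(np.sum((x - xm) * (y - ym)) / sxx)
    beta1 = float(ym - beta2 * xm)
    resid = y - (beta1 + beta2 * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma2 = ss_res / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0:
        p = 0.0 if beta2 != 0 else 1.0
    else:
        t = beta2 / se
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionResult(beta1, beta2, float(r2), p, se, n)


# --------------------------------------------------------------------------
# Case-control matching
# --------------------------------------------------------------------------


@dataclass
class MatchedPairs:
    """Per-case aggregated control values (same gender, age within tolerance)."""

    case_ids: list[str]
    case_values: np.ndarray
    control_values: np.ndarray
    n_controls: list[int]
    dropped_cases: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.case_ids)


def pair_case_controls(
    cases: Sequence[tuple[str, float, str]],
    controls: Sequence[tuple[str, float, str]],
    metric: dict[str, float],
    age_tol: float = 1.0,
    aggregate: Literal["median", "mean"] = "median",
) -> MatchedPairs:
    """Match each case to its gender- and age-matched controls.

    ``cases`` and ``controls`` are (id, age, gender) tuples; ``metric``
    maps subject id to the value being compared.  For each case the values
    of all controls with the same gender and |age difference| <= age_tol
    are aggregated (median by default) into a single control data point.
    Cases with zero matches are dropped and listed in ``dropped_cases``.
    """
    agg = np.median if aggregate == "median" else np.mean
    ids, cvals, ctrl_vals, n_ctrl, dropped = [], [], [], [], []
    for cid, cage, cgender in cases:
        matched = [
            metric[kid]
            for kid, kage, kgender in controls
            if kgender == cgender and abs(kage - cage) <= age_tol and kid in metric
        ]
        matched = [v for v in matched if np.isfinite(v)]
        if not matched:
            dropped.append(cid)
            continue
        ids.append(cid)
        cvals.append(metric.get(cid, np.nan))
        ctrl_vals.append(float(agg(matched)))
        n_ctrl.append(len(matched))
    return MatchedPairs(
        case_ids=ids,
        case_values=np.array(cvals, dtype=float),
        control_values=np.array(ctrl_vals, dtype=float),
        n_controls=n_ctrl,
        dropped_cases=dropped,
    )


def subsample_match_r2(
    values_a: Sequence[float],
    r2_a: Sequence[float],
    values_b: Sequence[float],
    r2_b: Sequence[float],
    seed: int | np.random.Generator = 0,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample both groups so their R^2 distributions match per histogram bin.

    Shared bins of ``bin_width``; in each bin min(count_a, count_b)
    observations are retained from each group, sampled without
    replacement.  Raises if the R^2 supports do not overlap at all.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    va, ra = np.asarray(values_a, float), np.asarray(r2_a, float)
    vb, rb = np.asarray(values_b, float), np.asarray(r2_b, float)
    lo = min(ra.min(), rb.min())
    hi = max(ra.max(), rb.max())
    edges = np.arange(np.floor(lo / bin_width) * bin_width,
                      hi + bin_width, bin_width)
    keep_a, keep_b = [], []
    for e0, e1 in zip(edges[:-1], edges[1:]):
        in_a = np.nonzero((ra >= e0) & (ra < e1))[0]
        in_b = np.nonzero((rb >= e0) & (rb < e1))[0]
        k = min(in_a.size, in_b.size)
        if k == 0:
            continue
        keep_a.append(rng.choice(in_a, k, replace=False))
        keep_b.append(rng.choice(in_b, k, replace=False))
    if not keep_a:
        raise ValueError("R^2 distributions have no overlapping bins")
    ia = np.sort(np.concatenate(keep_a))
    ib = np.sort(np.concatenate(keep_b))
    return va[ia], vb[ib]


# --------------------------------------------------------------------------
# Windowed group comparison
# --------------------------------------------------------------------------


@dataclass
class GroupComparison:
    centre_freqs: np.ndarray
    group_names: list[str]
    medians: dict[str, np.ndarray]
    sems: dict[str, np.ndarray]
    n: dict[str, np.ndarray]
    p_values: np.ndarray
    cluster_masks: dict[float, np.ndarray]
    test: str
    seed: int


def compare_groups(
    centre_freqs: np.ndarray,
    groups: dict[str, np.ndarray],
    test: Literal["KW", "WRS"] = "KW",
    alphas: Sequence[float] = (0.05, 0.01),
    min_cluster_len: int = 3,
    n_boot: int = 10000,
    seed: int = 0,
) -> GroupComparison:
    """Per-window group comparison with cluster-corrected significance.

    ``groups`` maps group name to a (n_subjects x n_windows) array of
    exponents (NaN = missing; dropped per window).  Per window: group
    medians with bootstrap SEMs, a K-W or rank-sum p-value (missing when a
    group has < 2 usable values), then run-length cluster masks at each
    alpha level independently.
    """
    centre_freqs = np.asarray(centre_freqs, dtype=float)
    names = list(groups)
    if test == "WRS" and len(names) != 2:
        raise ValueError("WRS requires exactly two groups")
    n_win = centre_freqs.size
    rng = np.random.default_rng(seed)

    medians = {g: np.full(n_win, np.nan) for g in names}
    sems = {g: np.full(n_win, np.nan) for g in names}
    counts = {g: np.zeros(n_win, dtype=int) for g in names}
    p_values = np.full(n_win, np.nan)

    for w in range(n_win):
        samples = {}
        for g in names:
            col = np.asarray(groups[g], dtype=float)[:, w]
            col = col[np.isfinite(col)]
            samples[g] = col
            counts[g][w] = col.size
            if col.size:
                med, sem = bootstrap_median_sem(col, n_iter=n_boot, seed=rng)
                medians[g][w] = med
                sems[g][w] = sem
        if all(samples[g].size >= 2 for g in names):
            if test == "KW":
                p_values[w] = kruskal_wallis_test([samples[g] for g in names])
            else:
                p_values[w] = rank_sum_test(samples[names[0]], samples[names[1]])

    masks = {
        float(a): cluster_significant(p_values, a, min_cluster_len) for a in alphas
    }
    return GroupComparison(
        centre_freqs=centre_freqs,
        group_names=names,
        medians=medians,
        sems=sems,
        n=counts,
        p_values=p_values,
        cluster_masks=masks,
        test=test,
        seed=seed,
    )
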