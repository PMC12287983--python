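"""Nonparametric group comparisons with bootstrap CIs.

Network metrics and behavior measures are heavily skewed, so all
comparisons are rank-based: Mann-Whitney U for two groups,
Kruskal-Wallis for three or more, chi-square for contingency tables,
pairwise Wilcoxon rank-sum with Bonferroni adjustment as the post hoc,
and percentile-bootstrap 95% CIs for differences of medians.  All
tests are two-sided.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    """One statistical comparison, JSON/CSV-serializable."""

    test: str
    groups: tuple
    statistic: float
    p_value: float
    n_per_group: tuple
    adjusted_p: Optional[float] = None
    median_difference: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    seed: Optional[int] = None
    n_boot: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = "|".join(str(g) for g in self.groups)
        d["n_per_group"] = "|".join(str(n) for n in self.n_per_group)
        return d


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def mann_whitney(
    group_a, group_b, names: tuple = ("a", "b")
) -> ComparisonResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples,
    tie-corrected normal approximation otherwise)."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires nonempty groups")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(
        test="mann_whitney",
        groups=names,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        median_difference=float(np.median(a) - np.median(b)),
    )


def kruskal_wallis(groups: Sequence, names: Optional[tuple] = None) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H across >=3 groups (chi-square, k-1 df)."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 3:
        raise ValueError("kruskal_wallis requires at least 3 groups")
    if any(g.size == 0 for g in cleaned):
        raise ValueError("kruskal_wallis requires nonempty groups")
    res = sps.kruskal(*cleaned)
    return ComparisonResult(
        test="kruskal_wallis",
        groups=names or tuple(range(1, len(cleaned) + 1)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=tuple(g.size for g in cleaned),
    )


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square of independence on a 2-D contingency table
    (no continuity correction), df = (r-1)(c-1)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chi_square expects a 2-D table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi_square: zero marginal in contingency table")
    res = sps.chi2_contingency(arr, correction=False)
    return ComparisonResult(
        test="chi_square",
        groups=tuple(f"row{i}" for i in range(arr.shape[0])),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=tuple(int(n) for n in arr.sum(axis=1)),
    )


def pairwise_wilcoxon_bonferroni(
    groups: Sequence, names: Optional[Sequence] = None
) -> list[ComparisonResult]:
    """All k(k-1)/2 pairwise rank-sum tests with Bonferroni adjustment.

    The multiplier is the number of pairwise comparisons within this
    family; adjusted p-values are capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    if names is None:
        names = [str(i) for i in range(1, len(groups) + 1)]
    k = len(groups)
    m = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            res = mann_whitney(groups[i], groups[j], names=(names[i], names[j]))
            res.test = "wilcoxon_rank_sum"
            res.adjusted_p = min(1.0, res.p_value * m)
            results.append(res)
    return results


def bootstrap_median_diff_ci(
    group_a,
    group_b,
    n_boot: int = 1000,
    seed: int = 0,
    names: tuple = ("a", "b"),
) -> ComparisonResult:
    """95% percentile-bootstrap CI for median(a) - median(b).

    Groups are resampled independently with replacement ``n_boot``
    times; the CI is the (2.5, 97.5) percentile of the resampled
    median differences.  Fully determined by ``seed``.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap needs at least 2 values per group")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = np.median(a[idx_a], axis=1) - np.median(b[idx_b], axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return ComparisonResult(
        test="bootstrap_median_diff",
        groups=names,
        statistic=float(np.median(a) - np.median(b)),
        p_value=float("nan"),
        n_per_group=(a.size, b.size),
        median_difference=float(np.median(a) - np.median(b)),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        n_boot=n_boot,
    )


def results_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as one row per test, for CSV export."""
    return pd.DataFrame([r.to_dict() for r in results])
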