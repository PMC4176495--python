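"""Nonparametric group comparison statistics.

The Mann-Whitney U test is the workhorse of every downstream comparison.
For small samples (min group size <= 8) the null distribution of U is
obtained by exact enumeration of all group labelings of the pooled values,
which remains valid under ties (midranks); larger samples use the normal
approximation with tie correction and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 8
EXACT_MAX_POOLED = 500
_EPS = 1e-9


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal"
    n1: int
    n2: int
    alternative: str


@dataclass
class GroupComparison:
    """Two-or-more-group comparison with a test statistic and summaries."""

    labels: list[str]
    ns: list[int]
    medians: list[float]
    means: list[float]
    statistic_name: str
    statistic: float
    p_value: float
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        assert all(n >= 1 for n in self.ns), "empty group"
        assert 0.0 <= self.p_value <= 1.0 + 1e-12

    def summary(self) -> dict:
        d = {"statistic": self.statistic_name, "value": self.statistic,
             "p_value": self.p_value, "alternative": self.alternative}
        for lab, n, med, mean in zip(self.labels, self.ns, self.medians, self.means):
            d[f"n_{lab}"] = n
            d[f"median_{lab}"] = med
            d[f"mean_{lab}"] = mean
        return d


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #{a_i > b_j} + 0.5 #{a_i == b_j}, via midranks."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2)


def _exact_p(pooled: np.ndarray, n1: int, u: float, alternative: str) -> float:
    """Exact permutation p-value of U, valid under ties.

    Counts, by dynamic programming over doubled midranks, how many of the
    C(n, n1) group labelings give each possible rank sum — equivalent to
    full enumeration but polynomial in n.
    """
    ranks2 = np.rint(2 * sps.rankdata(pooled)).astype(np.int64)
    n = len(pooled)
    # a size-n1 subset's doubled rank sum never exceeds the n1 largest ranks
    max_s = int(np.sort(ranks2)[-n1:].sum())
    # f[k, s] = number of k-subsets of the items seen so far with doubled
    # rank sum s (float64 counts; exact up to ~2^53 labelings)
    f = np.zeros((n1 + 1, max_s + 1))
    f[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            f[k, r:] += f[k - 1, : max_s + 1 - r]
    counts = f[n1]
    total = counts.sum()
    # doubled rank sum s corresponds to U = s/2 - n1(n1+1)/2
    u2 = 2 * u + n1 * (n1 + 1)  # doubled rank sum of the observed U
    s = np.arange(max_s + 1)
    p_le = counts[s <= u2 + _EPS].sum() / total
    p_ge = counts[s >= u2 - _EPS].sum() / total
    if alternative == "less":
        return float(p_le)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_p(pooled: np.ndarray, n1: int, n2: int, u: float, alternative: str) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = np.sqrt(var)
    if alternative == "less":
        return float(sps.norm.cdf((u - mu + 0.5) / sd))
    if alternative == "greater":
        return float(sps.norm.sf((u - mu - 0.5) / sd))
    # continuity correction toward the mean
    z = (u - mu - np.sign(u - mu) * 0.5) / sd if u != mu else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> MannWhitneyResult:
    """Mann-Whitney U test of two value sets.

    ``method='auto'`` uses exact enumeration when the smaller group has at
    most 8 values (valid under ties) and the tie-corrected normal
    approximation otherwise.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"bad alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    u = _u_statistic(a, b)
    if method == "auto":
        small = min(n1, n2) <= EXACT_MAX_N and n1 + n2 <= EXACT_MAX_POOLED
        method = "exact" if small else "normal"
    if method == "exact":
        p = _exact_p(pooled, n1, u, alternative)
    elif method == "normal":
        p = _normal_p(pooled, n1, n2, u, alternative)
    else:
        raise ValueError(f"bad method {method!r}")
    return MannWhitneyResult(u, p, method, n1, n2, alternative)


def compare_groups(
    values_by_label: dict[str, Sequence[float]],
    test_pair: tuple[str, str],
    alternative: str = "two-sided",
) -> GroupComparison:
    """Summarize labeled groups and test one pair with Mann-Whitney U."""
    labels = list(values_by_label)
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_label.items()}
    res = mann_whitney_u(arrays[test_pair[0]], arrays[test_pair[1]], alternative)
    return GroupComparison(
        labels=labels,
        ns=[len(arrays[k]) for k in labels],
        medians=[float(np.median(arrays[k])) for k in labels],
        means=[float(np.mean(arrays[k])) for k in labels],
        statistic_name=f"mann_whitney_u[{test_pair[0]} vs {test_pair[1]}]",
        statistic=res.u,
        p_value=res.p_value,
        alternative=alternative,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
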