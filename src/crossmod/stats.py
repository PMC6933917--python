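"""Shared statistical primitives.

Benjamini–Hochberg adjustment, one-way ANOVA, Tukey–Kramer HSD, Pearson
correlation test and the hypergeometric upper tail — the five tests every
downstream stage of the pipeline relies on. Distribution tails come from
scipy; the statistics themselves are computed here so each one can be
validated against an independent brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "PairwiseResult",
    "adjust_bh",
    "one_way_anova",
    "tukey_hsd",
    "pearson_cor_test",
    "hypergeom_tail",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the test statistic (F, r, q ... depending on the test),
    ``p`` its two-sided or upper-tail p-value, ``df`` the degrees of freedom
    (a tuple for F-type tests) and ``n`` the number of observations used.
    """

    statistic: float
    p: float
    df: tuple[float, ...] | float
    n: int


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey HSD contrast: group means difference and family-wise p."""

    group1: str
    group2: str
    diff: float
    q: float
    p: float
    n1: int
    n2: int


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserving.

    Ties are broken by original index (stable sort); the result does not
    depend on the tie-break. Output is capped at 1 and is elementwise >=
    the input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("adjust_bh expects a 1-D sequence of p-values")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def _group_arrays(values: Sequence[float], groups: Sequence) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return {g: values[groups == g] for g in dict.fromkeys(groups.tolist())}


def one_way_anova(values: Sequence[float], groups: Sequence) -> TestResult:
    """Fixed-effects one-way ANOVA F-test across the levels of ``groups``.

    F = MSB / MSW with the upper tail of F(k-1, n-k). A fully degenerate
    input (zero between- and within-group variance) returns F=0, p=1 so
    that scans over many synthetic modules never crash; zero within-group
    variance with distinct means returns F=inf, p=0.
    """
    by_group = _group_arrays(values, groups)
    k = len(by_group)
    if k < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    n = sum(v.size for v in by_group.values())
    df1, df2 = k - 1, n - k
    if df2 < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    grand = np.concatenate(list(by_group.values())).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    if ssw <= 0.0:
        if ssb <= 0.0:
            return TestResult(0.0, 1.0, (df1, df2), n)
        return TestResult(float("inf"), 0.0, (df1, df2), n)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), p, (df1, df2), n)


def tukey_hsd(values: Sequence[float], groups: Sequence) -> list[PairwiseResult]:
    """Tukey–Kramer honest significant difference over all group pairs.

    Uses the pooled within-group mean square and the studentized-range
    distribution with k groups and n-k residual df; unequal group sizes get
    the Kramer correction. Every group needs at least 2 observations.
    """
    by_group = _group_arrays(values, groups)
    k = len(by_group)
    if k < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    sizes = {g: v.size for g, v in by_group.items()}
    if min(sizes.values()) < 2:
        small = [str(g) for g, s in sizes.items() if s < 2]
        raise ValueError(f"groups with < 2 observations: {', '.join(small)}")
    n = sum(sizes.values())
    df = n - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / df
    results: list[PairwiseResult] = []
    for g1, g2 in combinations(by_group, 2):
        v1, v2 = by_group[g1], by_group[g2]
        diff = float(v1.mean() - v2.mean())
        se = np.sqrt(msw / 2.0 * (1.0 / v1.size + 1.0 / v2.size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df))
            if not np.isfinite(p):
                raise FloatingPointError(
                    f"studentized-range evaluation failed for pair ({g1}, {g2})"
                )
        results.append(
            PairwiseResult(str(g1), str(g2), diff, float(q),
                           float(min(max(p, 0.0), 1.0)), v1.size, v2.size)
        )
    return results


def pearson_cor_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the two-sided t-based significance test.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; exact
    collinearity (|r| = 1) yields p = 0. Zero variance in either input is a
    degenerate-input error — callers that must survive it catch ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson_cor_test requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd ** 2).sum())
    sy = np.sqrt((yd ** 2).sum())
    # relative tolerance: float jitter around a constant vector is still
    # degenerate (e.g. identical regression coefficients from lstsq)
    if sx <= 1e-10 * max(1.0, float(np.abs(x).max())) or \
       sy <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("degenerate input: zero variance")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    df = n - 2
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to float error
        return TestResult(r, 0.0, float(df), n)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(r, p, float(df), n)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated-set size, n the query size and
    k the observed overlap. Summation is done in log space over the support
    for numerical stability at large sizes.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if K > N or n > N or k > min(K, n):
        raise ValueError(
            f"inconsistent sizes: need 0 <= k <= min(K, n) <= N, got "
            f"k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logpmf = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(special.logsumexp(logpmf))))
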