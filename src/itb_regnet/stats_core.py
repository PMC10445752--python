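"""Statistical primitives shared by every pipeline stage.

The over-representation convention is fixed here once: tail="greater" means
P(X >= k) under the hypergeometric (R's ``phyper(k-1, ..., lower.tail=FALSE)``),
so no caller re-derives the off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats


class StatsValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    tail: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise StatsValidationError(f"p-value {self.p_value} outside [0,1]")


def hypergeom_overlap(
    overlap: int, set_a: int, set_b: int, universe: int, tail: str = "greater"
) -> TestResult:
    """Hypergeometric tail probability of an overlap between two sets.

    Draw |set_b| elements from a universe containing |set_a| marked ones;
    X is the number of marked elements drawn. tail="greater" gives P(X >= k),
    tail="less" gives P(X <= k).
    """
    if overlap < 0 or overlap > min(set_a, set_b):
        raise StatsValidationError(
            f"overlap {overlap} outside [0, min({set_a},{set_b})]"
        )
    if set_a > universe or set_b > universe:
        raise StatsValidationError("set size exceeds universe")
    dist = scipy.stats.hypergeom(universe, set_a, set_b)
    if tail == "greater":
        p = float(dist.sf(overlap - 1))
    elif tail == "less":
        p = float(dist.cdf(overlap))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(float(overlap), min(p, 1.0), tail, "hypergeometric")


def fisher_greater(table) -> TestResult:
    """One-sided Fisher's exact test (alternative: (1,1) cell is large)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise StatsValidationError(f"expected a 2x2 table, got {table.shape}")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.rint(table)) or (table < 0).any():
            raise StatsValidationError("table cells must be non-negative integers")
        table = np.rint(table).astype(int)
    odds, p = scipy.stats.fisher_exact(table, alternative="greater")
    return TestResult(float(odds), float(p), "greater", "fisher_exact")


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is <= ``exact_max_n`` and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections (the R ``wilcox.test`` behavior).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = (
        "exact" if (combined.size <= exact_max_n and not has_ties) else "asymptotic"
    )
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), "two-sided",
        f"wilcoxon_{method}",
    )


def two_proportion_greater(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """One-sided two-sample proportion test (p1 > p2), R ``prop.test`` contract.

    Chi-square statistic with Yates continuity correction; the one-sided
    p-value is the upper normal tail of sign(p1-p2-corrected) * sqrt(chi2).
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise StatsValidationError("require 0 <= x <= n and n > 0 in both groups")
    x = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    n = np.array([n1, n2], dtype=float)
    p_pool = (x1 + x2) / (n1 + n2)
    expected = np.column_stack([n * p_pool, n * (1.0 - p_pool)])
    yates = min(0.5, float(np.abs(x - expected).min()))
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (np.abs(x - expected) - yates) ** 2 / expected
    statistic = float(np.nansum(cells[np.isfinite(cells)]))
    delta = x1 / n1 - x2 / n2
    z = np.sign(delta) * np.sqrt(statistic)
    p = float(scipy.stats.norm.sf(z))
    return TestResult(statistic, min(p, 1.0), "greater", "prop_test_yates")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise StatsValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsValidationError("need equal-length vectors with n >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise StatsValidationError("rank variance is zero; rho undefined")
    rho, p = scipy.stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), "two-sided", "spearman")
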