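"""Exact-test primitives checked against full-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itb_regnet.stats_core import (
    StatsValidationError,
    bh_adjust,
    fisher_greater,
    hypergeom_overlap,
    spearman,
    two_proportion_greater,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# Enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(k, K, n, N, tail):
    """Tail probability by enumerating all C(N, n) draws from a labeled universe."""
    universe = list(range(N))
    marked = set(range(K))
    total = 0
    satisfying = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        overlap = len(marked.intersection(draw))
        if (tail == "greater" and overlap >= k) or (tail == "less" and overlap <= k):
            satisfying += 1
    return satisfying / total


def fisher_greater_oracle(table):
    """Sum hypergeometric point masses of tables at least as extreme in (1,1)."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    return sum(point(x) for x in range(a, min(r1, c1) + 1))


def wilcoxon_oracle(x, y):
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    nx, ny = len(x), len(y)
    combined = sorted(x + y)
    ranks_x = sum(combined.index(v) + 1 for v in x)
    u_obs = ranks_x - nx * (nx + 1) / 2
    mean_u = nx * ny / 2
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    all_ranks = range(1, nx + ny + 1)
    for assignment in itertools.combinations(all_ranks, nx):
        total += 1
        u = sum(assignment) - nx * (nx + 1) / 2
        if abs(u - mean_u) >= dev - 1e-9:
            count += 1
    return count / total


def bh_oracle(p):
    """Direct transcription of the step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

def test_hypergeom_worked_examples():
    assert hypergeom_overlap(4, 4, 5, 10).p_value == pytest.approx(5 / 210)
    assert hypergeom_overlap(0, 3, 4, 10, tail="greater").p_value == pytest.approx(1.0)
    assert hypergeom_overlap(2, 2, 2, 4, tail="less").p_value == pytest.approx(1.0)


def test_hypergeom_validates_inputs():
    with pytest.raises(StatsValidationError):
        hypergeom_overlap(5, 4, 5, 10)
    with pytest.raises(StatsValidationError):
        hypergeom_overlap(2, 11, 5, 10)


def test_fisher_worked_examples():
    assert fisher_greater([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 6)
    assert fisher_greater([[3, 0], [0, 3]]).p_value == pytest.approx(1 / 20)
    assert fisher_greater([[0, 5], [7, 0]]).p_value == pytest.approx(1.0)


def test_wilcoxon_worked_examples():
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)
    assert wilcoxon_rank_sum([1, 2], [3, 4]).p_value == pytest.approx(2 / 6)
    # identical values force the tie (asymptotic) path; no shift detectable
    r = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0])
    assert r.p_value == pytest.approx(1.0)
    assert r.method == "wilcoxon_asymptotic"


def test_two_proportion_contract():
    # values frozen from R prop.test(c(x1,x2), c(n1,n2), alternative="greater")
    r = two_proportion_greater(9, 10, 1, 10)
    assert r.statistic == pytest.approx(9.8, abs=1e-9)
    assert r.p_value == pytest.approx(0.0008725593, rel=1e-6)
    assert two_proportion_greater(3, 10, 3, 10).p_value >= 0.5
    assert two_proportion_greater(0, 5, 5, 5).p_value > 0.95


def test_bh_worked_examples():
    assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(StatsValidationError):
        bh_adjust([0.5, 1.5])


def test_spearman_examples():
    assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).statistic == pytest.approx(0.8)
    assert spearman([1, 2, 3], [10, 20, 30]).statistic == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)
    with pytest.raises(StatsValidationError):
        spearman([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Randomized oracle equivalence (small universes, exhaustive enumeration)
# ---------------------------------------------------------------------------

def test_hypergeom_matches_enumeration(rng):
    for _ in range(60):
        N = int(rng.integers(2, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        for tail in ("greater", "less"):
            expected = hypergeom_tail_oracle(k, K, n, N, tail)
            got = hypergeom_overlap(k, K, n, N, tail=tail).p_value
            assert got == pytest.approx(expected, rel=1e-9), (k, K, n, N, tail)


def test_hypergeom_tail_complement_identity(rng):
    for _ in range(30):
        N = int(rng.integers(2, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(1, min(K, n) + 1))
        total = (
            hypergeom_overlap(k, K, n, N, tail="greater").p_value
            + hypergeom_overlap(k - 1, K, n, N, tail="less").p_value
        )
        assert total == pytest.approx(1.0, rel=1e-9)


def test_fisher_matches_enumeration(rng):
    for _ in range(60):
        table = rng.integers(0, 7, size=(2, 2))
        expected = fisher_greater_oracle(table.tolist())
        got = fisher_greater(table).p_value
        assert got == pytest.approx(expected, rel=1e-9), table


def test_wilcoxon_exact_matches_enumeration(rng):
    for _ in range(40):
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 6))
        pooled = rng.choice(100, size=nx + ny, replace=False).astype(float)
        x, y = list(pooled[:nx]), list(pooled[nx:])
        expected = wilcoxon_oracle(x, y)
        got = wilcoxon_rank_sum(x, y).p_value
        assert got == pytest.approx(expected, rel=1e-9), (x, y)


def test_bh_matches_step_up_definition(rng):
    for _ in range(50):
        m = int(rng.integers(1, 12))
        p = np.round(rng.uniform(size=m), 3)
        assert bh_adjust(p) == pytest.approx(bh_oracle(list(p)), rel=1e-12)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
@settings(deadline=None, derandomize=True)
def test_bh_dominates_input_and_monotone(p):
    p = np.asarray(p)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    srt = bh_adjust(np.sort(p))
    assert (np.diff(srt) >= -1e-12).all()


@given(st.data())
@settings(deadline=None, derandomize=True, max_examples=60)
def test_hypergeom_tails_partition_unit_mass(data):
    N = data.draw(st.integers(2, 12))
    K = data.draw(st.integers(1, N))
    n = data.draw(st.integers(1, N))
    k = data.draw(st.integers(1, min(K, n)))
    total = (
        hypergeom_overlap(k, K, n, N, tail="greater").p_value
        + hypergeom_overlap(k - 1, K, n, N, tail="less").p_value
    )
    assert total == pytest.approx(1.0, rel=1e-9)
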