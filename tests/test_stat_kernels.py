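"""Kernel correctness against small-instance independent oracles."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverscope.stat_kernels import (
    bh_adjust,
    binomial_two_sided,
    correlation_test,
    cox_score_test,
    fit_cox,
    logrank,
    rank_sum,
)

# ---------------------------------------------------------------------------
# oracles


def binom_two_sided_oracle(k, n, p0=0.5):
    """Sum of pmf over outcomes no more probable than the observed one."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


def rank_sum_permutation_oracle(x, y, alternative):
    """Exact permutation distribution of the Mann-Whitney U statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs_u = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        us.append(
            sum(1 for a in grp for b in rest if a > b)
            + 0.5 * sum(1 for a in grp for b in rest if a == b)
        )
    us = np.asarray(us)
    p_greater = np.mean(us >= obs_u)
    p_less = np.mean(us <= obs_u)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def bh_oracle(p):
    """Step-up adjustment computed from the textbook formula."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_pos in range(m - 1, -1, -1):
        idx = order[rank_pos]
        running_min = min(running_min, p[idx] * m / (rank_pos + 1))
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# binomial


@pytest.mark.parametrize(
    "k,n,expected",
    [
        (10, 10, 2 * 0.5**10),  # all one direction
        (5, 10, 1.0),  # perfectly balanced
        (8, 10, 112 / 1024),  # tail enumeration
    ],
)
def test_binomial_known_values(k, n, expected):
    assert binomial_two_sided(k, n).p_value == pytest.approx(expected, abs=1e-12)


def test_binomial_matches_enumeration_oracle():
    for n in range(1, 26):
        for k in range(n + 1):
            got = binomial_two_sided(k, n).p_value
            want = binom_two_sided_oracle(k, n)
            assert got == pytest.approx(want, abs=1e-10), (k, n)


def test_binomial_symmetry_and_errors():
    for n in (3, 10, 17):
        for k in range(n + 1):
            assert binomial_two_sided(k, n).p_value == pytest.approx(
                binomial_two_sided(n - k, n).p_value, abs=1e-12
            )
    with pytest.raises(ValueError):
        binomial_two_sided(0, 0)


# ---------------------------------------------------------------------------
# rank-sum


def test_rank_sum_exact_example():
    res = rank_sum([5, 6, 7], [1, 2, 3], alternative="greater")
    assert res.p_value == pytest.approx(1 / 20)


def test_rank_sum_degenerate_and_errors():
    res = rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.degenerate and res.p_value == 1.0
    with pytest.raises(ValueError):
        rank_sum([], [1.0])


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 2), (5, 4)])
@pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
def test_rank_sum_exact_equals_permutation_enumeration(n1, n2, alternative, rng):
    x = rng.normal(size=n1)
    y = rng.normal(size=n2)
    got = rank_sum(x, y, alternative).p_value
    want = rank_sum_permutation_oracle(x, y, alternative)
    assert got == pytest.approx(want, abs=1e-10)


def test_rank_sum_two_sided_bounded_by_twice_one_sided(rng):
    for _ in range(25):
        x = rng.normal(size=rng.integers(2, 12))
        y = rng.normal(size=rng.integers(2, 12))
        two = rank_sum(x, y, "two_sided").p_value
        bound = 2 * min(rank_sum(x, y, "greater").p_value, rank_sum(x, y, "less").p_value)
        assert two <= bound + 1e-12


# ---------------------------------------------------------------------------
# correlation


def test_correlation_known_structure(rng):
    x = rng.normal(size=40)
    assert correlation_test(x, 2 * x + 1, "pearson").estimate == pytest.approx(1.0)
    assert correlation_test(x, np.exp(x), "spearman").estimate == pytest.approx(1.0)
    # orthogonal mean-centered vectors
    a = np.array([1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0])
    assert correlation_test(a, b, "pearson").estimate == pytest.approx(0.0, abs=1e-12)


def test_correlation_degenerate_flag():
    res = correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert res.degenerate


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.04, 0.5], [0.08, 0.5]),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


def test_bh_matches_step_up_oracle(rng):
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_monotone_properties(p):
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()  # order-preserving
    assert (adj >= np.asarray(p) - 1e-12).all()  # adjustment never lowers p
    assert (bh_adjust(adj) >= adj - 1e-12).all()  # re-application never lowers
    assert (adj <= 1.0).all()
    if len(p) == 1:
        assert adj[0] == pytest.approx(p[0])  # m=1 identity


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups():
    t = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], float)
    e = np.ones(10)
    g = np.array([0] * 5 + [1] * 5)
    res = logrank(t, e, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_label_symmetry(rng):
    t = rng.exponential(10, size=60)
    e = rng.integers(0, 2, size=60).astype(float)
    if e.sum() == 0:
        e[0] = 1
    g = rng.integers(0, 2, size=60)
    a = logrank(t, e, g)
    b = logrank(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_logrank_zero_events_degenerate():
    res = logrank([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], [0, 0, 1, 1])
    assert res.degenerate and res.p_value == 1.0


@pytest.mark.parametrize("k_groups", [2, 4])
def test_logrank_matches_lifelines(k_groups, rng):
    from lifelines.statistics import multivariate_logrank_test

    for _ in range(5):
        n = 80
        t = rng.exponential(10, size=n)
        e = (rng.uniform(size=n) < 0.7).astype(float)
        g = rng.integers(0, k_groups, size=n)
        if len(np.unique(g)) < k_groups:
            continue
        ours = logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-8)


def test_logrank_agrees_with_permutation_null(rng):
    """Planted HR: analytic p within 0.02 of a permutation-null p."""
    n = 200
    g = np.repeat([0, 1], n // 2)
    lam = np.where(g == 1, 3.0, 1.0) * 0.05
    t = rng.exponential(1.0 / lam)
    cens = rng.uniform(0, 40, size=n)
    e = (t <= cens).astype(float)
    tt = np.minimum(t, cens)
    obs = logrank(tt, e, g).statistic
    n_perm = 2000
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = logrank(tt, e, rng.permutation(g)).statistic
    p_perm = float(np.mean(null >= obs))
    p_analytic = logrank(tt, e, g).p_value
    assert abs(p_analytic - p_perm) < 0.02


# ---------------------------------------------------------------------------
# Cox


def test_cox_score_equals_logrank_on_untied_data(rng):
    n = 120
    t = rng.exponential(10, size=n)
    assert len(np.unique(t)) == n
    e = (rng.uniform(size=n) < 0.8).astype(float)
    g = rng.integers(0, 2, size=n)
    score = cox_score_test(t, e, g).statistic
    lr = logrank(t, e, g).statistic
    assert score == pytest.approx(lr, abs=1e-6)


def test_cox_null_and_planted_recovery(rng):
    n = 2000
    z = rng.integers(0, 2, size=n).astype(float)
    # null: hazard independent of covariate
    t0 = rng.exponential(10, size=n)
    fit0 = fit_cox({"z": z}, t0, np.ones(n))
    assert abs(fit0.coef["z"]) < 0.1
    # planted HR = 2, ~50% events
    lam = 0.05 * np.where(z == 1, 2.0, 1.0)
    t_event = rng.exponential(1.0 / lam)
    cens = rng.uniform(0, 30, size=n)
    fit = fit_cox({"z": z}, np.minimum(t_event, cens), (t_event <= cens).astype(float))
    assert fit.coef["z"] == pytest.approx(np.log(2), abs=0.1)
    assert fit.hazard_ratio["z"] == pytest.approx(np.exp(fit.coef["z"]), rel=1e-9)
    assert fit.ci_lower["z"] < fit.hazard_ratio["z"] < fit.ci_upper["z"]


def test_cox_input_validation(rng):
    n = 30
    t = rng.exponential(10, size=n)
    e = np.ones(n)
    with pytest.raises(ValueError, match="constant"):
        fit_cox({"z": np.ones(n)}, t, e)
    with pytest.raises(ValueError, match="events"):
        fit_cox({"z": rng.normal(size=n)}, t, np.zeros(n))
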