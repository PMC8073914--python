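"""Statistical tests used across the screening stages.

The conventions fixed here are the ones every stage relies on:

* the dominant-direction binomial test is two-sided in the exact
  "sum of outcomes no more probable than the observed one" sense;
* the rank-sum test uses the exact permutation distribution for small
  untied groups and the tie/continuity-corrected normal approximation
  otherwise;
* Benjamini-Hochberg is the step-up adjustment, pooled wherever a stage
  says so;
* the log-rank statistic is the classic observed-minus-expected
  chi-square over pooled event times, supporting k >= 2 groups;
* Cox models use Efron tie handling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "CoxFit",
    "binomial_two_sided",
    "rank_sum",
    "correlation_test",
    "bh_adjust",
    "logrank",
    "cox_score_test",
    "fit_cox",
]

#: below this minimum group size (and with no ties) rank_sum enumerates the
#: exact permutation distribution instead of the normal approximation
EXACT_RANKSUM_THRESHOLD = 8

ALTERNATIVES = ("two_sided", "greater", "less")
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str = "two_sided"
    n: int = 0
    estimate: float | None = None  # correlation coefficient where applicable
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CoxFit:
    """Per-covariate Cox partial-likelihood fit summary (Efron ties)."""

    coef: pd.Series
    hazard_ratio: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_value: pd.Series
    log_likelihood: float
    ties: str = "efron"
    n: int = 0
    n_events: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_value,
            }
        )


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials.

    The two-sided p sums the probabilities of all outcomes whose point
    mass does not exceed that of the observed count (the standard exact
    convention, symmetric at p0 = 0.5).
    """
    if n < 1:
        raise ValueError("binomial test requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    res = stats.binomtest(int(k), int(n), p0, alternative="two-sided")
    return TestResult(statistic=float(k), p_value=float(res.pvalue), n=int(n))


def rank_sum(x, y, alternative: str = "two_sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test between two samples.

    Exact permutation distribution when the smaller group has at most
    ``EXACT_RANKSUM_THRESHOLD`` observations and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum requires two non-empty groups")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return TestResult(
            statistic=float(x.size * y.size / 2.0),
            p_value=1.0,
            alternative=alternative,
            n=pooled.size,
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (min(x.size, y.size) <= EXACT_RANKSUM_THRESHOLD and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(
        x, y, alternative=_SCIPY_ALT[alternative], method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        n=pooled.size,
    )


def correlation_test(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation test requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation test requires finite values")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return TestResult(
            statistic=np.nan, p_value=1.0, n=x.size, estimate=np.nan, degenerate=True
        )
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(statistic=float(r), p_value=float(p), n=x.size, estimate=float(r))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def logrank(times, events, groups) -> TestResult:
    """K-group log-rank test (chi-square with k-1 degrees of freedom).

    At each pooled event time the observed events per group are compared
    with the expectation under equal hazards; the covariance of the
    observed-minus-expected vector uses the hypergeometric form.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    if not (times.size == events.size == groups.size):
        raise ValueError("times, events and groups must have equal length")
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank requires at least two groups")
    if not np.isin(events, [0.0, 1.0]).all():
        raise ValueError("events must be 0/1")
    n_events = int(events.sum())
    if n_events == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=times.size, degenerate=True)

    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], gidx[order]
    event_times = np.unique(t[e == 1])

    omE = np.zeros(k)
    cov = np.zeros((k, k))
    for tau in event_times:
        at_risk = t >= tau
        n_at_risk = float(at_risk.sum())
        n_j = np.bincount(g[at_risk], minlength=k).astype(float)
        dying = at_risk & (t == tau) & (e == 1)
        d = float(dying.sum())
        d_j = np.bincount(g[dying], minlength=k).astype(float)
        exp_j = d * n_j / n_at_risk
        omE += d_j - exp_j
        if n_at_risk > 1:
            frac = d * (n_at_risk - d) / (n_at_risk - 1.0)
            p_j = n_j / n_at_risk
            cov += frac * (np.diag(p_j) - np.outer(p_j, p_j))

    # drop one group: the O-E vector sums to zero
    v = omE[:-1]
    V = cov[:-1, :-1]
    try:
        chi2 = float(v @ np.linalg.solve(V, v))
    except np.linalg.LinAlgError:
        chi2 = float(v @ np.linalg.pinv(V) @ v)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return TestResult(statistic=chi2, p_value=p, n=times.size)


def logrank_direction(times, events, carrier_mask) -> str:
    """Which group fares better: carriers or non-carriers.

    Returns ``"better"`` when carriers have fewer observed than expected
    events (their Kaplan-Meier curve dominates), else ``"worse"``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    carrier = np.asarray(carrier_mask, dtype=bool)
    omE = 0.0
    for tau in np.unique(times[events == 1]):
        at_risk = times >= tau
        d = float((at_risk & (times == tau) & (events == 1)).sum())
        d_c = float((at_risk & (times == tau) & (events == 1) & carrier).sum())
        n = float(at_risk.sum())
        n_c = float((at_risk & carrier).sum())
        omE += d_c - d * n_c / n
    return "better" if omE <= 0 else "worse"


def cox_score_test(times, events, covariate) -> TestResult:
    """Cox partial-likelihood score test at beta = 0 for one covariate.

    On untied data this equals the two-group log-rank chi-square when the
    covariate is a binary group indicator (the classic equivalence).  Ties
    are handled in the Breslow sense.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    z = np.asarray(covariate, dtype=float)
    score = 0.0
    info = 0.0
    for tau in np.unique(times[events == 1]):
        at_risk = times >= tau
        d_mask = at_risk & (times == tau) & (events == 1)
        d = float(d_mask.sum())
        zbar = z[at_risk].mean()
        zvar = float(np.mean((z[at_risk] - zbar) ** 2))
        score += float(z[d_mask].sum()) - d * zbar
        info += d * zvar
    if info <= 0:
        return TestResult(statistic=0.0, p_value=1.0, n=times.size, degenerate=True)
    chi2 = score**2 / info
    return TestResult(statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)), n=times.size)


def fit_cox(covariate_table: pd.DataFrame, times, events, alpha: float = 0.05) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Parameters
    ----------
    covariate_table : numeric design matrix, one row per subject.
    times, events : follow-up time and 0/1 event indicator.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    X = pd.DataFrame(covariate_table).astype(float).reset_index(drop=True)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    n_events = int(events.sum())
    if n_events < X.shape[1] + 1:
        raise ValueError(
            f"{n_events} events insufficient for {X.shape[1]} covariates"
        )
    df = X.copy()
    df["_time"] = times
    df["_event"] = events
    fitter = CoxPHFitter(alpha=alpha)
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = fitter.summary
    return CoxFit(
        coef=summ["coef"],
        hazard_ratio=summ["exp(coef)"],
        ci_lower=np.exp(summ["coef lower 95%"]),
        ci_upper=np.exp(summ["coef upper 95%"]),
        p_value=summ["p"],
        log_likelihood=float(fitter.log_likelihood_),
        ties="efron",
        n=len(df),
        n_events=n_events,
    )
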