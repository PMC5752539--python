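"""Independently coded brute-force references used only by the tests.

Deliberately naive implementations (explicit loops, enumeration, direct
linear algebra) kept separate from the package's optimized code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats


def cox_efron_loglik(beta: float, x, times, events) -> float:
    """Naive Efron partial log-likelihood via explicit risk-set loops."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d_idx = np.nonzero((times == t) & (events == 1))[0]
        risk = np.nonzero(times >= t)[0]
        d = len(d_idx)
        sum_w_risk = sum(math.exp(beta * x[i]) for i in risk)
        sum_w_d = sum(math.exp(beta * x[i]) for i in d_idx)
        ll += beta * x[d_idx].sum()
        for ell in range(d):
            ll -= math.log(sum_w_risk - (ell / d) * sum_w_d)
    return ll


def cox_beta_bruteforce(x, times, events, lo=-20.0, hi=20.0) -> float:
    """MLE of the univariate Cox coefficient by direct 1-D optimization of
    the naive Efron likelihood."""
    res = optimize.minimize_scalar(
        lambda b: -cox_efron_loglik(b, x, times, events),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def logrank_bruteforce(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank statistic via explicit per-event-time tables."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n_a = (ta >= t).sum()
        n_b = (tb >= t).sum()
        d_a = ((ta == t) & (ea == 1)).sum()
        d_b = ((tb == t) & (eb == 1)).sum()
        n = n_a + n_b
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def km_curve(times, events):
    """Kaplan-Meier survival curve and Greenwood terms at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    event_times = np.unique(times[events == 1])
    surv = []
    greenwood = []
    s = 1.0
    gw = 0.0
    for t in event_times:
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            gw += d / (n_at_risk * (n_at_risk - d))
        surv.append(s)
        greenwood.append(gw)
    return event_times, np.array(surv), np.array(greenwood)


def km_median_ci_bruteforce(times, events, alpha=0.05):
    """Median survival and its CI from the log-log (exp-Greenwood)
    pointwise confidence band, each curve inverted at 0.5."""
    t, s, gw = km_curve(times, events)
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log(-np.log(s))
        se = np.sqrt(gw) / np.abs(np.log(s))
        lower_band = np.exp(-np.exp(theta + z * se))  # below S(t)
        upper_band = np.exp(-np.exp(theta - z * se))  # above S(t)
    lower_band = np.where(s <= 0, 0.0, np.where(s >= 1, 1.0, lower_band))
    upper_band = np.where(s <= 0, 0.0, np.where(s >= 1, 1.0, upper_band))

    def invert(curve):
        hit = np.nonzero(curve <= 0.5)[0]
        return float(t[hit[0]]) if len(hit) else float("inf")

    # the lower band crosses 0.5 earlier -> lower bound of the median CI
    return invert(s), invert(lower_band), invert(upper_band)


def bh_bruteforce(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def fisher_bruteforce(table) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def chi2_uncorrected_bruteforce(table) -> float:
    """Textbook sum((O-E)^2/E) over the four cells, no correction."""
    t = np.asarray(table, float)
    total = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / total
            stat += (t[i, j] - e) ** 2 / e
    return stat


def rwr_linear_solve(adjacency: np.ndarray, seed_idx, r: float) -> np.ndarray:
    """RWR fixed point by direct dense linear solve of
    (I - (1-r) W) p = r p0."""
    a = np.asarray(adjacency, float)
    n = a.shape[0]
    deg = a.sum(axis=0)
    w = a / np.where(deg == 0, 1.0, deg)
    p0 = np.zeros(n)
    p0[list(seed_idx)] = 1.0 / len(seed_idx)
    return np.linalg.solve(np.eye(n) - (1 - r) * w, r * p0)
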