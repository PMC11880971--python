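"""Independent brute-force oracles used by the test suite.

Each function here recomputes a statistic from its definition (enumeration,
direct formula, hand product-limit), deliberately avoiding the code paths
and libraries the package uses for the same quantity.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Enumerates every 2×2 table with the observed margins, computes each
    table's point probability from factorials, and sums those not exceeding
    the observed table's probability (with a small relative tolerance for
    floating ties, matching the conventional definition).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1); table [[x, r1-x],[c1-x, ...]]
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - (c1 - x) + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= p_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def silhouette_direct(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from its textbook definition: s(i) =
    (b(i) − a(i)) / max(a(i), b(i)) with a = mean intra-cluster distance to
    the other members, b = min over other clusters of the mean distance."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    s_vals = []
    for i in range(len(X)):
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s_vals.append(0.0)
            continue
        a = d[own].sum() / (n_own - 1)
        b = min(d[labels == other].mean() for other in uniq
                if other != labels[i])
        s_vals.append((b - a) / max(a, b))
    return float(np.mean(s_vals))


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as U / (n1·n2) by pairwise comparison, ties counting 1/2."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def km_curve(times, events):
    """Product-limit survival estimate: list of (event time, S(t))."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    s = 1.0
    out = []
    for t in np.unique(times[events]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        out.append((float(t), s))
    return out


def logrank_chi2(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank statistic by direct O−E accumulation."""
    ta = np.asarray(times_a, float)
    ea = np.asarray(events_a, bool)
    tb = np.asarray(times_b, float)
    eb = np.asarray(events_b, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in all_t:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(((ta == t) & ea).sum())
        db = int(((tb == t) & eb).sum())
        d = da + db
        if n < 2:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if V == 0:
        return float("nan")
    return (O - E) ** 2 / V
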