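"""Independent brute-force reference implementations for the test suite.

Deliberately naive and written straight from the definitions; they share
no code with the package.
"""

from __future__ import annotations

import itertools
import math
import statistics

ATOL = 1e-9


def oracle_pairs(values, days, mode):
    out = []
    for i in range(len(values) - 1):
        if mode == "record" or days[i + 1] - days[i] == 1:
            out.append((values[i], values[i + 1]))
    return out


def oracle_pct_var(values, days, mode):
    pairs = oracle_pairs(values, days, mode)
    if not pairs:
        return None
    changed = sum(1 for a, b in pairs if abs(a - b) > ATOL)
    return 100.0 * changed / len(pairs)


def oracle_rvar(values, unit_step, plus_one=False):
    span = max(values) - min(values)
    if plus_one:
        span += unit_step
    return span / unit_step


def oracle_ivi(values, days, unit_step, mode="calendar", plus_one=False):
    if len(values) < 2:
        return None
    pct_var = oracle_pct_var(values, days, mode)
    if pct_var is None:
        return None
    rvar = oracle_rvar(values, unit_step, plus_one)
    if rvar == 0:
        return 0.0
    return pct_var / rvar


def oracle_pct_zero(values):
    if not values:
        return None
    return 100.0 * sum(1 for v in values if abs(v) <= ATOL) / len(values)


def oracle_cv(values, ddof=1):
    if len(values) < 2:
        return None
    mean = statistics.fmean(values)
    if mean <= ATOL:
        return None
    if ddof == 1:
        sd = statistics.stdev(values)
    else:
        sd = statistics.pstdev(values)
    return 100.0 * sd / mean


def _sign(diff):
    if diff > ATOL:
        return 1
    if diff < -ATOL:
        return -1
    return 0


def oracle_trend(values, days, mode="calendar"):
    """Sign-transition rate over adjacent consecutive-day pairs."""
    if len(values) < 3:
        return None
    signed = []
    for i in range(len(values) - 1):
        if mode == "record" or days[i + 1] - days[i] == 1:
            signed.append((i, _sign(values[i + 1] - values[i])))
    comparisons = [
        (a, b) for (i, a), (j, b) in zip(signed, signed[1:]) if mode == "record" or j == i + 1
    ]
    if not comparisons:
        return None
    changes = sum(1 for a, b in comparisons if a != b)
    return 100.0 * changes / len(comparisons)


def oracle_spearman(x, y):
    """Spearman rho via average ranks and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = statistics.fmean(rx), statistics.fmean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def oracle_mannwhitney_exact(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (no ties).

    Returns (U for x, p). p sums the null probability of all group
    assignments whose U is at least as far from mn/2 as the observed U.
    """
    m, n = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires no ties"

    def u_of(subset):
        # subset holds the values assigned to the first group
        u = 0
        rest = [v for v in combined if v not in subset]
        for a in subset:
            for b in rest:
                if a > b:
                    u += 1
        return u

    u_obs = sum(1 for a in x for b in y if a > b)
    center = m * n / 2
    extreme = 0
    total = 0
    for subset in itertools.combinations(combined, m):
        total += 1
        if abs(u_of(set(subset)) - center) >= abs(u_obs - center) - ATOL:
            extreme += 1
    return u_obs, extreme / total


def oracle_population_mean(cohort_days):
    """Group-by-date mean from (date, value) tuples."""
    by_date = {}
    for date, value in cohort_days:
        by_date.setdefault(date, []).append(value)
    return {d: statistics.fmean(v) for d, v in by_date.items()}
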