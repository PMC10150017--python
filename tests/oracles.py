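"""Independent brute-force oracles used by the test suite.

These deliberately use naive O(n^2) enumeration and textbook sum formulas,
sharing no code with the package implementations they check.
"""

import math


def pearson_bruteforce(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def point_biserial_bruteforce(x, y):
    """Mean-difference formula: r_pb = (m1 - m0) * sqrt(p*q) / s_y."""
    n = len(x)
    g1 = [b for a, b in zip(x, y) if a == 1]
    g0 = [b for a, b in zip(x, y) if a == 0]
    p = len(g1) / n
    my = sum(y) / n
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)  # population SD
    m1 = sum(g1) / len(g1)
    m0 = sum(g0) / len(g0)
    return (m1 - m0) * math.sqrt(p * (1 - p)) / sy


def kendall_tau_b_bruteforce(x, y):
    """tau-b by enumerating all pairs and counting tie groups."""
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    n0 = n * (n - 1) // 2

    def tie_term(v):
        counts = {}
        for a in v:
            counts[a] = counts.get(a, 0) + 1
        return sum(t * (t - 1) // 2 for t in counts.values())

    n1, n2 = tie_term(x), tie_term(y)
    return (conc - disc) / math.sqrt((n0 - n1) * (n0 - n2))


def best_subset_rss(y, X, q):
    """Exhaustive best size-q OLS subset by residual sum of squares."""
    import itertools

    import numpy as np

    cols = list(X.columns)
    best, best_rss = None, math.inf
    for combo in itertools.combinations(cols, q):
        A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in combo])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ beta) ** 2))
        if rss < best_rss - 1e-10:
            best, best_rss = set(combo), rss
    return best, best_rss
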