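"""Independent brute-force oracles shared by the test modules.

These deliberately restate the statistics as literal textbook procedures,
independent of the package's implementations.
"""

import numpy as np


def bh_oracle(p):
    """Benjamini–Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def es_oracle(metric, hit, p=1.0):
    """Weighted running-sum enrichment score by explicit step-through."""
    n = len(metric)
    nh = sum(hit)
    w = [abs(m) ** p for m in metric]
    hit_sum = sum(wi for wi, h in zip(w, hit) if h)
    run, best = 0.0, 0.0
    for i in range(n):
        if hit[i]:
            run += w[i] / hit_sum if hit_sum > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def fisher_enum(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    p_obs = comb(row1, a) * comb(n - row1, col1 - a) / denom
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = comb(row1, x) * comb(n - row1, col1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total
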