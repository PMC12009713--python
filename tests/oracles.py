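"""Independent oracles the implementation is checked against."""

import numpy as np


def brute_force_ks(x, y):
    """Independent exact two-sample KS oracle by full enumeration.

    For distinct pooled values, D depends only on which sorted positions
    belong to the first sample; the exact p-value is the fraction of all
    C(m+n, m) equally likely interleavings whose D is at least the
    observed one.
    """
    from itertools import combinations
    from math import comb

    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    pooled = np.sort(np.concatenate([x, y]))
    assert len(np.unique(pooled)) == m + n, "oracle assumes distinct values"

    def d_of(member_positions):
        members = set(member_positions)
        fx = fy = 0
        d = 0.0
        for i in range(m + n):
            if i in members:
                fx += 1
            else:
                fy += 1
            d = max(d, abs(fx / m - fy / n))
        return d

    observed = d_of(np.searchsorted(pooled, np.sort(x)))
    count = sum(
        1 for pos in combinations(range(m + n), m)
        if d_of(pos) >= observed - 1e-12
    )
    return observed, count / comb(m + n, m)


def bh_oracle(p):
    """Hand-coded BH step-up: adjusted_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        out[i] = running
    return out
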