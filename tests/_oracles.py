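"""Independent reference computations used to cross-check the library.

Everything here is deliberately naive — explicit loops, grid searches and
log-linear algebra — and shares no code path with the implementations it
checks.
"""

from __future__ import annotations

import numpy as np


def grid_search_t1(ti, s, n_grid: int = 25, rounds: int = 5):
    """Brute-force SSE minimisation of S = A - B exp(-TI/T1*) on a
    successively refined (A, B, T1*) grid; returns (A, B, T1*, T1)."""
    ti = np.asarray(ti, float)
    s = np.asarray(s, float)
    a_lo, a_hi = 0.2 * abs(s[-1]), 3.0 * abs(s[-1]) + 1.0
    b_lo, b_hi = 0.2 * abs(s[-1] - s[0]), 3.0 * abs(s[-1] - s[0]) + 1.0
    t_lo, t_hi = 50.0, 6000.0
    best = None
    for _ in range(rounds):
        a_g = np.linspace(a_lo, a_hi, n_grid)
        b_g = np.linspace(b_lo, b_hi, n_grid)
        t_g = np.linspace(t_lo, t_hi, n_grid)
        model = (a_g[:, None, None, None]
                 - b_g[None, :, None, None]
                 * np.exp(-ti[None, None, None, :] / t_g[None, None, :, None]))
        sse = ((model - s) ** 2).sum(axis=-1)
        ia, ib, it = np.unravel_index(np.argmin(sse), sse.shape)
        a, b, t = a_g[ia], b_g[ib], t_g[it]
        da, db, dt = a_g[1] - a_g[0], b_g[1] - b_g[0], t_g[1] - t_g[0]
        a_lo, a_hi = a - 2 * da, a + 2 * da
        b_lo, b_hi = b - 2 * db, b + 2 * db
        t_lo, t_hi = max(t - 2 * dt, 1.0), t + 2 * dt
    return a, b, t, t * (b / a - 1.0)


def loglinear_adc(b, s):
    """ADC from unweighted linear regression of log S on b."""
    b = np.asarray(b, float)
    s = np.asarray(s, float)
    slope, _ = np.polyfit(b, np.log(s), 1)
    return -slope


def icc_2k_double_loop(x):
    """ICC(2,k) from an explicitly looped two-way ANOVA decomposition."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)
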