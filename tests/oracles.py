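"""Independent straight-line oracles, written as naive loops.

These deliberately re-derive each statistic from its definition, without
touching the package implementations they check.
"""

import numpy as np
from scipy import stats


def tmm_factor_pair(yk, yr, nk, nr, trim_m=0.30, trim_a=0.05):
    """Naive doubly-trimmed weighted mean of M-values, one sample vs ref."""
    m_vals, a_vals, w_vals = [], [], []
    for g in range(len(yk)):
        if yk[g] > 0 and yr[g] > 0:
            pk, pr = yk[g] / nk, yr[g] / nr
            m_vals.append(np.log2(pk / pr))
            a_vals.append(0.5 * np.log2(pk * pr))
            w_vals.append((nk - yk[g]) / (nk * yk[g]) + (nr - yr[g]) / (nr * yr[g]))
    m_vals, a_vals, w_vals = map(np.asarray, (m_vals, a_vals, w_vals))
    n = len(m_vals)
    rank_m = stats.rankdata(m_vals)
    rank_a = stats.rankdata(a_vals)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for g in range(n):
        if lo_m <= rank_m[g] <= hi_m and lo_a <= rank_a[g] <= hi_a:
            num += m_vals[g] / w_vals[g]
            den += 1.0 / w_vals[g]
    return 2.0 ** (num / den)


def bh_stepup(p):
    """Textbook step-up BH adjustment."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def ols_t_test(y, x, contrast):
    """Per-gene ordinary-least-squares t-test of a contrast."""
    x = np.asarray(x, float)
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    out = []
    for row in np.asarray(y, float):
        beta = xtx_inv @ x.T @ row
        resid = row - x @ beta
        s2 = resid @ resid / (n - p)
        est = contrast @ beta
        se = np.sqrt(contrast @ xtx_inv @ contrast * s2)
        t = est / se
        out.append((est, t, 2 * stats.t.sf(abs(t), n - p)))
    return np.asarray(out)


def gsva_scores(x, in_set, tau=1.0):
    """Step-by-step GSVA: Gaussian kernel CDF, ranks, weighted random walk."""
    x = np.asarray(x, float)
    p, n = x.shape
    z = np.zeros_like(x)
    for i in range(p):
        h = np.std(x[i], ddof=1) / 4.0
        if h == 0:
            h = 1e-8
        for j in range(n):
            z[i, j] = np.mean([stats.norm.cdf((x[i, j] - x[i, k]) / h) for k in range(n)])
    m = int(np.sum(in_set))
    scores = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: -z[i, j])
        weights = []
        for pos, i in enumerate(order, start=1):
            weights.append(abs(p / 2.0 - pos) ** tau if in_set[i] else 0.0)
        wsum = sum(weights)
        run, vmax, vmin = 0.0, 0.0, 0.0
        for pos, i in enumerate(order, start=1):
            if in_set[i]:
                run += weights[pos - 1] / wsum
            else:
                run -= 1.0 / (p - m)
            vmax, vmin = max(vmax, run), min(vmin, run)
        scores.append(vmax + vmin)
    return np.asarray(scores)


def nb_mean_var(mu, phi):
    return mu, mu + phi * mu**2
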