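"""Independent brute-force reference implementations used by the tests.

These deliberately recompute results in the most literal way possible —
naive loops, direct enumeration — so they share no code path with the
package implementations they check.
"""

import math
from itertools import product

import numpy as np


def naive_label_events(feats, thresholds, mode, two_muscle_rule_only=False):
    """Literal re-implementation of the epoch labeling rule.

    For each epoch: count muscles strictly above their base threshold; fire
    on >= 2.  Otherwise decay each erector spinae threshold linearly (half
    at 90 deg forward / 30 deg sideways, clamped) and fire if either ES
    amplitude strictly exceeds its decayed threshold.  Invalid epochs never
    fire.
    """
    labels = []
    for f in feats:
        if not f.valid:
            labels.append(False)
            continue
        over = 0
        for m in thresholds.muscles:
            if f.p90_rms_mv.get(m, 0.0) > thresholds.base[mode][m]:
                over += 1
        fired = over >= 2
        if not fired and not two_muscle_rule_only:
            for m in ("ESR", "ESL"):
                base = thresholds.base[mode][m]
                frac_f = min(abs(f.fwd_deg), 90.0) / 90.0
                frac_s = min(abs(f.side_deg), 30.0) / 30.0
                decayed = min(base * (1 - 0.5 * frac_f), base * (1 - 0.5 * frac_s))
                if f.p90_rms_mv.get(m, 0.0) > decayed:
                    fired = True
        labels.append(fired)
    return labels


def fisher_p_by_product_enumeration(table):
    """Exact conditional p by Cartesian-product enumeration with rejection."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    log_const = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
    )

    def lp(cells):
        return log_const - sum(math.lgamma(v + 1) for v in cells)

    p_obs = lp(t.ravel())
    r, c = t.shape
    # enumerate the free (r-1) x (c-1) block; margins determine the rest
    ranges = [range(int(min(rows[i], cols[j])) + 1) for i in range(r - 1) for j in range(c - 1)]
    total = 0.0
    for free in product(*ranges):
        m = np.zeros((r, c), dtype=int)
        m[: r - 1, : c - 1] = np.asarray(free).reshape(r - 1, c - 1)
        m[: r - 1, c - 1] = rows[: r - 1] - m[: r - 1, : c - 1].sum(axis=1)
        m[r - 1, :] = cols - m[: r - 1, :].sum(axis=0)
        if (m < 0).any():
            continue
        q = lp(m.ravel())
        if q <= p_obs + 1e-9:
            total += math.exp(q)
    return min(1.0, total)


def fisher_class_pvalues_2xc(row_margins, col_margins):
    """Vectorized exact p for every 2 x c table with the given margins.

    Enumerates the first row over a meshgrid (the second row is determined),
    filters invalid cell values, and maps each table to the summed
    probability of all tables no more probable than it.  Returns
    (tables, pvalues) with tables of shape (K, 2, c).
    """
    from scipy.special import gammaln

    r1, r2 = row_margins
    cols = np.asarray(col_margins, dtype=int)
    c = len(cols)
    grids = np.meshgrid(*[np.arange(min(r1, cols[j]) + 1) for j in range(c - 1)], indexing="ij")
    first = np.stack([g.ravel() for g in grids], axis=1) if c > 1 else np.zeros((1, 0), int)
    last = r1 - first.sum(axis=1)
    ok = (last >= 0) & (last <= cols[c - 1])
    first = first[ok]
    last = last[ok]
    top = np.concatenate([first, last[:, None]], axis=1)
    bottom = cols[None, :] - top
    ok = (bottom >= 0).all(axis=1)
    top, bottom = top[ok], bottom[ok]
    tables = np.stack([top, bottom], axis=1)  # (K, 2, c)
    n = r1 + r2
    log_const = gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(cols + 1).sum() - gammaln(n + 1)
    lps = log_const - gammaln(tables + 1.0).sum(axis=(1, 2))
    order = np.argsort(lps)
    sorted_lp = lps[order]
    cum = np.cumsum(np.exp(sorted_lp))
    idx = np.searchsorted(sorted_lp, lps + 1e-9, side="right") - 1
    pvals = np.minimum(1.0, cum[idx])
    return tables, pvals


def power_by_simulation(n, delta, sd, alpha, rng, n_sim=20000):
    """Monte-Carlo power of the two-sample two-sided t-test."""
    from scipy import stats

    a = rng.normal(delta, sd, size=(n_sim, n))
    b = rng.normal(0.0, sd, size=(n_sim, n))
    t, p = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(p < alpha))
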