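"""Independent brute-force oracles, kept free of any package internals."""

import math

import numpy as np
from scipy import stats


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up executed literally from its definition:

    q(i) = min over j >= i of p(j) * m / j on the sorted p-values, capped at 1.
    """
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def pooled_t_pvalue(a, b):
    """Two-sided pooled-variance t-test from first principles."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((x - m1) ** 2 for x in a)
    ss2 = sum((x - m2) ** 2 for x in b)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def pearson_r2_from_sums(x, y):
    """R^2 computed from raw sums (n, Sx, Sy, Sxx, Syy, Sxy) only."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(u * v for u, v in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return num * num / den


def count_summary_recount(sig_sets_by_region, sig_combined, regions):
    """Brute-force recount of the per-region significance summary."""
    any_region = set().union(*sig_sets_by_region.values()) if sig_sets_by_region else set()
    out = {}
    for r in regions:
        s = sig_sets_by_region[r]
        only = {p for p in s if all(p not in sig_sets_by_region[o] for o in regions if o != r)}
        out[("total", r)] = len(s)
        out[("single_region_only", r)] = len(only)
    multi = {p for p in any_region
             if sum(p in sig_sets_by_region[r] for r in regions) > 1}
    out[("total", "at_least_one_region")] = len(any_region)
    out[("total", "multiple_regions")] = len(multi)
    out[("total", "combined")] = len(sig_combined)
    out[("only_significant_in_combined", "combined")] = len(sig_combined - any_region)
    return out
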