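"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity with the plainest possible algorithm
(explicit loops, enumeration, closed forms), deliberately sharing no code
with the package, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_breakpoint(x, y, min_segment=3):
    """Evaluate every admissible split with np.polyfit; first-best tie rule.

    Returns (break_index, total_rss, profile list).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    best_k, best_rss, profile = None, None, []
    for k in range(min_segment - 1, n - min_segment):
        rss = 0.0
        for seg in (slice(0, k + 1), slice(k + 1, n)):
            coef = np.polyfit(x[seg], y[seg], 1)
            resid = y[seg] - np.polyval(coef, x[seg])
            rss += float(np.sum(resid**2))
        profile.append(rss)
        if best_rss is None or rss < best_rss - 0.0:
            if best_rss is None or rss < best_rss:
                best_k, best_rss = k, rss
    return best_k, best_rss, profile


def brute_force_tmm_factors(counts, trim_m=0.30, trim_a=0.05):
    """Plain-loop TMM factors: doubly rank-trimmed weighted mean of M-values.

    ``counts`` is an ndarray genes x samples; the reference is the column
    whose 75th-percentile count proportion is closest to the mean of those
    percentiles; weights are inverse approximate M variances on the
    proportion scale; factors rescaled to geometric mean one.
    """
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    uqs = [
        float(np.quantile([counts[g, j] / lib[j] for g in range(counts.shape[0])], 0.75))
        for j in range(counts.shape[1])
    ]
    mean_uq = sum(uqs) / len(uqs)
    ref = min(range(counts.shape[1]), key=lambda j: abs(uqs[j] - mean_uq))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ms, was, ws = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            ms.append(math.log2(po / pr))
            was.append(0.5 * math.log2(po * pr))
            ws.append(1.0 / ((1.0 - po) / po + (1.0 - pr) / pr))
        n = len(ms)
        if n == 0:
            factors.append(1.0)
            continue
        lo_m, lo_a = int(math.floor(n * trim_m)), int(math.floor(n * trim_a))
        order_m = sorted(range(n), key=lambda i: (ms[i], i))
        order_a = sorted(range(n), key=lambda i: (was[i], i))
        rank_m = {idx: pos + 1 for pos, idx in enumerate(order_m)}
        rank_a = {idx: pos + 1 for pos, idx in enumerate(order_a)}
        num = den = 0.0
        for i in range(n):
            if lo_m < rank_m[i] <= n - lo_m and lo_a < rank_a[i] <= n - lo_a:
                num += ws[i] * ms[i]
                den += ws[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    factors = np.asarray(factors)
    log_gm = np.mean(np.log(factors))
    return factors / np.exp(log_gm)


def bitmask_venn_counts(sets):
    """Region counts of a Venn partition via per-gene membership bitmasks."""
    names = list(sets)
    members = {n: set(sets[n]) for n in names}
    universe = set().union(*members.values())
    counts: dict[tuple, int] = {}
    for g in universe:
        mask = tuple(n for n in names if g in members[n])
        counts[mask] = counts.get(mask, 0) + 1
    return counts


def exhaustive_permutation_p(values_a, values_b):
    """Exact two-sided permutation p for |mean difference| via enumeration."""
    pooled = list(values_a) + list(values_b)
    n_a = len(values_a)
    obs = abs(np.mean(values_a) - np.mean(values_b))
    hits = total = 0
    for combo in combinations(range(len(pooled)), n_a):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(np.mean(a) - np.mean(b)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def hypergeom_tail_p(k, N, K, n):
    """Upper-tail hypergeometric P(X >= k) by direct summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total
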