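"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the implementation paths they check: direct
enumeration of hypergeometric tables, heterozygote configurations, and
binomial outcomes, plus naive O(n*m) interval intersection.
"""
from __future__ import annotations

import itertools
import math
from fractions import Fraction


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with the same
    margins, summing probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (
            Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = table_prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= obs * (1 + Fraction(1, 10**12)):
            total += p
    return float(min(total, 1))


def hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by enumeration over heterozygote counts of the same
    parity with fixed allele counts, weights ∝ n! 2^nAB /(nAA! nAB! nBB!)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    weights = {}
    for nab in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        if naa < 0 or nbb < 0:
            continue
        weights[nab] = Fraction(
            math.factorial(n) * 2**nab,
            math.factorial(naa) * math.factorial(nab) * math.factorial(nbb),
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


def binomial_tail_oracle(k, n, p=0.5):
    """One-sided P(X >= k) by direct summation (exact for p = 1/2)."""
    if p == 0.5:
        return float(sum(Fraction(math.comb(n, x), 2**n) for x in range(k, n + 1)))
    return float(
        sum(math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1))
    )


def wilcoxon_signed_rank_oracle(diffs):
    """Exact two-sided signed-rank p by enumeration of all sign vectors
    (no ties, no zeros)."""
    import numpy as np

    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = {}
    order = sorted(range(n), key=lambda i: abs(diffs[i]))
    for r, i in enumerate(order, 1):
        ranks[i] = r
    w_obs = sum(ranks[i] for i in range(n) if diffs[i] > 0)
    total = 2**n
    stats = []
    for signs in itertools.product((0, 1), repeat=n):
        stats.append(sum(r for i, r in ranks.items() if signs[i]))
    mean = n * (n + 1) / 4
    dev_obs = abs(w_obs - mean)
    count = sum(1 for w in stats if abs(w - mean) >= dev_obs - 1e-9)
    return count / total


def naive_interval_overlap(query_lo, query_hi, intervals):
    """Half-open overlap by linear scan; returns matching payloads."""
    out = []
    for start, end, payload in intervals:
        if start < query_hi and query_lo < end:
            out.append(payload)
    return out


def pwm_best_score_dist(matrix_logratio, window_len):
    """Exhaustive distribution of the best forward+reverse score over all
    windows of ``window_len`` (4**window_len enumeration).

    ``matrix_logratio``: (L, 4) log2(p/bg).  Returns a sorted list of the
    best scores of every window.
    """
    import numpy as np

    lr = np.asarray(matrix_logratio)
    L = lr.shape[0]
    rc = lr[::-1, ::-1]
    best_scores = []
    for window in itertools.product(range(4), repeat=window_len):
        best = -math.inf
        for t in range(window_len - L + 1):
            sub = window[t : t + L]
            fwd = sum(lr[i, b] for i, b in enumerate(sub))
            rev = sum(rc[i, b] for i, b in enumerate(sub))
            best = max(best, fwd, rev)
        best_scores.append(best)
    return sorted(best_scores)


def minority_fraction_expectation(n, p=0.5, n_sim=200_000, seed=0):
    """Monte-Carlo expectation and sd of min(X, n-X)/n, X ~ Binomial(n,p)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    x = rng.binomial(n, p, size=n_sim)
    frac = np.minimum(x, n - x) / n
    return float(frac.mean()), float(frac.std())
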