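"""Independent brute-force oracles used to cross-check the package.

Everything here is written position-by-position / pair-by-pair with no
shared code with the implementation under test, so agreement is
evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(scores, hit_flags, weight):
    """Enrichment score by explicit position-by-position running sum.

    ``scores`` must already be in ranked (descending) order and
    ``hit_flags`` mark set membership at each position.
    """
    scores = list(scores)
    hit_flags = list(hit_flags)
    n = len(scores)
    n_hit = sum(bool(h) for h in hit_flags)
    total_hit_weight = sum(abs(s) ** weight for s, h in zip(scores, hit_flags) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            if total_hit_weight > 0:
                running += abs(s) ** weight / total_hit_weight
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def brute_force_ssgsea(ordered_values, hit_flags, exponent):
    """ssGSEA score by explicit enumeration of the running difference.

    ``ordered_values`` are expression values sorted decreasing.
    """
    n = len(ordered_values)
    n_hit = sum(bool(h) for h in hit_flags)
    rank_values = [n - i for i in range(n)]  # position 0 -> N
    total = sum(rank_values[i] ** exponent for i in range(n) if hit_flags[i])
    cum_hit = 0.0
    cum_miss = 0.0
    score = 0.0
    for i in range(n):
        if hit_flags[i]:
            cum_hit += rank_values[i] ** exponent / total
        else:
            cum_miss += 1.0 / (n - n_hit)
        score += cum_hit - cum_miss
    return score


def pair_count_auc(scores, labels):
    """AUC as the fraction of concordant (positive, negative) pairs,
    ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def linear_interp_percentile(values, q):
    """q-th percentile with the linear interpolation rule
    (the 'linear' definition: index = q/100 * (n-1))."""
    v = sorted(values)
    n = len(v)
    idx = q / 100.0 * (n - 1)
    lo = int(np.floor(idx))
    hi = int(np.ceil(idx))
    if lo == hi:
        return v[lo]
    frac = idx - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def permutation_pearson_p(x, y, n_perm, seed):
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    obs = abs(corr(x, y))
    count = 0
    for _ in range(n_perm):
        if abs(corr(x, rng.permutation(y))) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)
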