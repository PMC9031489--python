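"""Naive O(n^2) reference implementations of the entropy estimators and of
plug-in mutual information, written as literal transcriptions of their
definitions with explicit Python loops.

These exist solely as independent cross-checks for the vectorized
estimators in :mod:`neohrv.features` and :mod:`neohrv.model`; they share
no code with them and are far too slow for production epochs.
"""

from __future__ import annotations

import math


def _cheb(u, v) -> float:
    return max(abs(a - b) for a, b in zip(u, v))


def sample_entropy_naive(x, m=2, r_abs=None) -> float:
    x = list(map(float, x))
    n = len(x)
    if n < m + 2 or not r_abs or r_abs <= 0:
        return float("nan")
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]
    b = sum(1 for i in range(len(tm)) for j in range(i + 1, len(tm))
            if _cheb(tm[i], tm[j]) < r_abs)
    a = sum(1 for i in range(len(tm1)) for j in range(i + 1, len(tm1))
            if _cheb(tm1[i], tm1[j]) < r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def approximate_entropy_naive(x, m=2, r_abs=None) -> float:
    x = list(map(float, x))
    n = len(x)
    if n < m + 2 or not r_abs or r_abs <= 0:
        return float("nan")

    def phi(mm):
        t = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for u in t:
            c = sum(1 for v in t if _cheb(u, v) < r_abs) / len(t)
            total += math.log(c)
        return total / len(t)

    return phi(m) - phi(m + 1)


def distribution_entropy_naive(x, m=2, tau=1, n_bins=512) -> float:
    x = list(map(float, x))
    n = len(x)
    if n < m + 1:
        return float("nan")
    t = [[x[i + k * tau] for k in range(m)] for i in range(n - (m - 1) * tau)]
    if len(t) < 2:
        return float("nan")
    d = [_cheb(t[i], t[j]) for i in range(len(t)) for j in range(i + 1, len(t))]
    dmax = max(d)
    if dmax == 0:
        return 0.0
    counts = [0] * n_bins
    for dist in d:
        idx = min(int(dist / dmax * n_bins), n_bins - 1)
        counts[idx] += 1
    total = len(d)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h / math.log2(n_bins)


def mutual_information_naive(a, b) -> float:
    a = list(a)
    b = list(b)
    n = len(a)
    vals_a = sorted(set(a))
    vals_b = sorted(set(b))
    mi = 0.0
    for va in vals_a:
        for vb in vals_b:
            pab = sum(1 for x, y in zip(a, b) if x == va and y == vb) / n
            if pab == 0:
                continue
            pa = sum(1 for x in a if x == va) / n
            pb = sum(1 for y in b if y == vb) / n
            mi += pab * math.log(pab / (pa * pb))
    return mi


def roc_auc_naive(scores, truth) -> float:
    """Exhaustive pairwise rank comparison: P(s+ > s-) + P(tie)/2."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
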