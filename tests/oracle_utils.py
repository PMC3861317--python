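"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (math.comb, exhaustive
enumeration) and deliberately shares no code path with the package.
"""

from __future__ import annotations

from itertools import permutations
from math import comb

import numpy as np


def hyper_sf_ge(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n) by direct summation."""
    lo = max(a, 0, n - (N - K))
    hi = min(K, n)
    if lo > hi:
        return 0.0 if a > 0 else 1.0
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)) / denom


def bh_stepup(pvals, m: int) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values over m hypotheses."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    running = 1.0
    for rank_from_top in range(len(p) - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        q[i] = running
    return q


def _tally(arrangement, D, model, min_count, fisher_threshold) -> int:
    hzma = [i for i, g in enumerate(arrangement) if g == 2]
    hzca = [i for i, g in enumerate(arrangement) if g == 0]
    qual = []
    for g in range(D.shape[1]):
        cnt = sum(bool(D[i, g]) for i in hzma)
        if model == "recessive_perm":
            ok = cnt >= 1
        else:
            ok = cnt >= min_count
            if ok and model == "rg2":
                c = sum(bool(D[i, g]) for i in hzca)
                p = hyper_sf_ge(cnt, len(hzma) + len(hzca), cnt + c, len(hzma))
                ok = p < fisher_threshold
        if ok:
            qual.append(g)
    return sum(1 for i in hzma if any(D[i, g] for g in qual))


def exhaustive_perm_p(
    dosages, D, model="rg1", min_count=2, fisher_threshold=0.1
) -> float:
    """Exact permutation p by enumerating every distinct arrangement of the
    genotype multiset (feasible for <= 8 subjects)."""
    dosages = tuple(int(x) for x in dosages)
    t_obs = _tally(dosages, D, model, min_count, fisher_threshold)
    arrangements = set(permutations(dosages))
    n_ge = sum(
        _tally(a, D, model, min_count, fisher_threshold) >= t_obs
        for a in arrangements
    )
    return n_ge / len(arrangements)


def auc_by_pairs(null_scores, case_scores) -> float:
    """AUC by direct pairwise enumeration; lower score = more case-like."""
    total = 0.0
    for c in case_scores:
        for n in null_scores:
            total += 1.0 if c < n else (0.5 if c == n else 0.0)
    return total / (len(case_scores) * len(null_scores))
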