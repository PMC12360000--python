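"""Independent brute-force oracles used to validate the package's statistics.

These are deliberately naive re-derivations (full enumeration, direct
formula transcription) kept separate from the package code paths they
check.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def ranksum_p_exact(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Every way of labelling the pooled observations as x-group is equally
    likely under the null; p = 2 * min(P(U <= u_obs), P(U >= u_obs)),
    capped at 1, with U the Mann-Whitney statistic of the x group.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.asarray(x + y)
    order = pooled.argsort(kind="stable")
    ranks = np.empty_like(pooled)
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n, m = len(x), len(y)

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2.0

    u_obs = u_of(range(n))
    total = comb(n + m, n)
    n_le = n_ge = 0
    for idx in combinations(range(n + m), n):
        u = u_of(idx)
        if u <= u_obs:
            n_le += 1
        if u >= u_obs:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the margin.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (the common exact
    two-sided convention).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> float:
        # hypergeometric pmf for cell (0,0) = k
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def tmm_reference(counts, logratio_trim=0.30, abundance_trim=0.05) -> np.ndarray:
    """Reference TMM transcription: trimmed, variance-weighted mean log ratio.

    Written directly from the published definition: per sample against a
    reference column (75th-percentile-closest-to-mean), keep genes positive
    in both, drop the most extreme ``logratio_trim`` of M values and
    ``abundance_trim`` of A values from each tail by rank, average the
    remaining M weighted by inverse delta-method variance, exponentiate,
    and rescale to unit geometric mean.
    """
    x = np.asarray(counts, dtype=float)
    lib = x.sum(axis=0)
    upper_q = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_col = int(np.abs(upper_q - upper_q.mean()).argmin())
    out = []
    for j in range(x.shape[1]):
        obs, ref = x[:, j], x[:, ref_col]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / lib[j]) / (r / lib[ref_col]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref_col]))
        w = 1.0 / ((lib[j] - o) / (lib[j] * o) + (lib[ref_col] - r) / (lib[ref_col] * r))
        if np.max(np.abs(m)) < 1e-6:
            out.append(1.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
        rank_m = _average_rank(m)
        rank_a = _average_rank(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        out.append(2.0 ** (np.sum(m[sel] * w[sel]) / np.sum(w[sel])))
    out = np.asarray(out)
    return out / np.exp(np.mean(np.log(out)))


def _average_rank(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks
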