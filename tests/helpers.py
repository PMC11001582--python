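"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library code paths they check: plain-Python
loops and textbook formulas only.
"""

from __future__ import annotations

import math

import numpy as np


def threshold_run_oracle(dff, noise_sd, threshold_mult=2.0, min_duration=3, merge_gap=0):
    """Exhaustive O(T) scan for maximal runs above threshold.

    Returns a list of (onset, peak, peak_value) tuples, with optional merging
    of runs separated by a gap shorter than ``merge_gap`` frames before the
    duration criterion.
    """
    thr = threshold_mult * noise_sd
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(list(dff) + [-math.inf]):  # sentinel closes a trailing run
        if v > thr and not in_run:
            in_run = True
            start = i
        elif v <= thr and in_run:
            in_run = False
            runs.append((start, i))
    if merge_gap > 0:
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    events = []
    for s, e in runs:
        if e - s >= min_duration:
            peak = s
            for j in range(s, e):
                if dff[j] > dff[peak]:
                    peak = j
            events.append((s, peak, float(dff[peak])))
    return events


def welch_t_oracle(a, b):
    """Textbook two-sided Welch t-test: returns (t, df, p)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def bh_stepup_oracle(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, direct from the formula:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), in the original order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_tail_oracle(N, K, n, k):
    """P(overlap >= k) for a query of size n against a set of size K in a
    universe of size N, by explicit combinatorial summation."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total
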