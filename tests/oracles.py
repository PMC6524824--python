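"""Independent brute-force oracles used to check the implementation.

These deliberately mirror the written definitions step by step (explicit
loops, exact rational arithmetic) and share no code with the package.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def ssgsea_cell_oracle(values: pd.Series, members, tau: float,
                       min_overlap: int = 1):
    """Enrichment score of one set in one cell by a direct double loop.

    Genes with missing values are dropped; the remaining genes are walked
    in decreasing-value order (ties by gene id) accumulating the in-set
    cumulative weight fraction and the out-of-set cumulative count
    fraction; the score is the sum of their differences over all steps.
    Returns None where the set has too little (or total) overlap.
    """
    obs = [(g, v) for g, v in values.items() if np.isfinite(v)]
    if not obs:
        raise ValueError("empty universe")
    ranked = sorted(obs, key=lambda gv: (-gv[1], gv[0]))
    n = len(ranked)
    members = set(members)
    m = sum(1 for g, _ in ranked if g in members)
    if m < min_overlap or m == n:
        return None
    sum_w = 0.0
    for i, (g, _) in enumerate(ranked):
        if g in members:
            sum_w += float(n - i) ** tau
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i, (g, _) in enumerate(ranked):
        if g in members:
            p_in += float(n - i) ** tau / sum_w
        else:
            p_out += 1.0 / (n - m)
        es += p_in - p_out
    return es


def fisher_twosided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration at fixed margins,
    in exact rational arithmetic (minimum-likelihood convention)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))
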