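"""Independent brute-force oracles for the small-sample statistics.

These deliberately share no code with the package implementations: the
rank tests enumerate every label assignment of the pooled sample, and the
Hardy-Weinberg oracle enumerates genotype configurations with exact
rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np


def _u_stat(x, y) -> float:
    """U for sample x: number of (xi, yj) pairs with xi > yj (+0.5 ties)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_exact_p(x, y) -> float:
    """Two-sided Mann-Whitney p by exhaustive arrangement enumeration."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    mean = n1 * n2 / 2
    dev = abs(_u_stat(x, y) - mean)
    total = extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in set(combo)]
        total += 1
        if abs(_u_stat(xs, ys) - mean) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def _d_stat(x, y) -> float:
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / len(xs)
    fy = np.searchsorted(ys, grid, side="right") / len(ys)
    return float(np.max(np.abs(fx - fy)))


def ks_exact(x, y) -> tuple[float, float]:
    """Two-sample KS statistic and exact enumeration p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    d_obs = _d_stat(x, y)
    pooled = np.sort(np.concatenate([x, y]))
    total = extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(combo)] = True
        total += 1
        if _d_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            extreme += 1
    return d_obs, extreme / total


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided HWE exact p via genotype-configuration enumeration.

    Conditional on n and the minor-allele count, every configuration
    (a, b, c) has probability proportional to n! / (a! b! c!) * 2^b; the
    p-value sums configurations no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    probs: dict[int, Fraction] = {}
    for b in range(n + 1):
        for c in range(n + 1 - b):
            a = n - b - c
            if 2 * c + b != n_alt:
                continue
            probs[b] = Fraction(
                factorial(n), factorial(a) * factorial(b) * factorial(c)
            ) * Fraction(2) ** b
    total = sum(probs.values())
    obs = probs[n_het]
    tail = sum(w for w in probs.values() if w <= obs)
    return float(tail / total)


def count_window_contributions(table, anchors, window_size, n_per_side) -> int:
    """Brute-force count of (site, anchor) pairs falling in any flank window."""
    total = 0
    maf = table.maf()
    for a in anchors:
        if hasattr(a, "span_start"):
            chrom, s, e = a.chrom, a.span_start, a.span_end
        else:
            chrom, s = a[0], a[1]
            e = s + 1
        for i in range(table.n_sites):
            if str(table.chrom[i]) != chrom or np.isnan(maf[i]):
                continue
            if table.minor_count()[i] < 1:
                continue
            p = int(table.pos0[i])
            if s - n_per_side * window_size <= p < s:
                total += 1
            elif e <= p < e + n_per_side * window_size:
                total += 1
    return total
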