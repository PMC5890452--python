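"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration or direct
definition, independent of the library's implementation paths.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np


# --- genotype likelihood oracle ------------------------------------------


def best_genotype_bruteforce(depths, eps: float):
    """Enumerate all 21 unordered genotype pairs of the 6-allele space and
    return (pair, loglik) maximizing the multinomial log-likelihood."""
    depths = list(depths)
    best = None
    best_ll = -math.inf
    for a, b in combinations_with_replacement(range(6), 2):
        ll = 0.0
        for x, n in enumerate(depths):
            if n == 0:
                continue
            if a == b:
                p = (1 - eps) if x == a else eps / 5
            else:
                p = (1 - eps) / 2 + eps / 10 if x in (a, b) else eps / 5
            ll += n * math.log(p)
        if ll > best_ll + 1e-12:
            best_ll = ll
            best = (a, b)
    return best, best_ll


# --- exact Fisher tests by enumeration ------------------------------------


def _log_table_prob(table) -> float:
    t = np.asarray(table, dtype=np.int64)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    lg = math.lgamma
    val = sum(lg(x + 1) for x in r) + sum(lg(x + 1) for x in c) - lg(n + 1)
    val -= sum(lg(x + 1) for x in t.ravel())
    return val


def enumerate_tables_2xn(row_sums, col_sums):
    """Yield every 2 x N non-negative integer table with the given margins."""
    r1, r2 = row_sums
    cols = list(col_sums)

    def rec(j, rem_r1, prefix):
        if j == len(cols) - 1:
            a = rem_r1
            b = cols[j] - a
            if 0 <= a <= cols[j] and b >= 0:
                yield prefix + [(a, b)]
            return
        for a in range(min(rem_r1, cols[j]) + 1):
            b = cols[j] - a
            if b < 0:
                continue
            yield from rec(j + 1, rem_r1 - a, prefix + [(a, b)])

    for cells in rec(0, r1, []):
        t = np.array(cells, dtype=np.int64).T
        if t[1].sum() == r2:
            yield t


def exact_fisher_2xn(table, tol: float = 1e-9) -> float:
    """Exact Fisher P for a 2 x N table: total probability of all tables
    with the observed margins whose probability is <= the observed one."""
    t = np.asarray(table, dtype=np.int64)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or np.any(t.sum(axis=1) == 0):
        return 1.0
    obs = _log_table_prob(t)
    total = 0.0
    for cand in enumerate_tables_2xn(t.sum(axis=1), t.sum(axis=0)):
        lp = _log_table_prob(cand)
        if lp <= obs + tol:
            total += math.exp(lp)
    return min(total, 1.0)


# --- IBD filter oracle -----------------------------------------------------


def ibd_filter_bruteforce(genotypes, alleles, taxon_pairs, min_ratio=2.0) -> str:
    """Literal re-implementation of the per-allele match/mismatch rule.

    genotypes: (n_taxa, 2) site-allele pairs with -1 missing.
    Returns 'confirmed', 'ibd1' or 'fail'.
    """
    match = {a: 0 for a in range(len(alleles))}
    mismatch = {a: 0 for a in range(len(alleles))}
    present = set()
    for i, j in taxon_pairs:
        gi = [int(x) for x in genotypes[i]]
        gj = [int(x) for x in genotypes[j]]
        if gi[0] < 0 or gj[0] < 0:
            continue
        carriers_i = set(gi)
        carriers_j = set(gj)
        present |= carriers_i | carriers_j
        for a in carriers_i | carriers_j:
            both = a in carriers_i and a in carriers_j
            if both:
                match[a] += 1
            else:
                mismatch[a] += 1
    n_ok = 0
    for a in match:
        if mismatch[a] == 0:
            if match[a] > 0:
                n_ok += 1
        elif match[a] / mismatch[a] >= min_ratio:
            n_ok += 1
    if n_ok >= 2:
        return "confirmed"
    if len(present) <= 1:
        return "ibd1"
    return "fail"


# --- inbreeding coefficient oracle ----------------------------------------


def inbreeding_bruteforce(genotypes, maf) -> float:
    """Direct evaluation of F = (O - E) / (N - E), E = sum(1 - 2 p q)."""
    O = 0
    N = 0
    E = 0.0
    for g, p in zip(genotypes, maf):
        if g[0] < 0:
            continue
        N += 1
        if g[0] == g[1]:
            O += 1
        E += 1.0 - 2.0 * p * (1.0 - p)
    if N == 0:
        raise ValueError("no genotyped sites")
    if abs(N - E) < 1e-12:
        return float("nan")
    return (O - E) / (N - E)
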