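"""Segregation-test filter: hybrid chi-square / Monte-Carlo Fisher exact test.

For each pair of alleles at a candidate site, a 2 × N contingency table of
per-taxon read depths (allele 1 in row 1, allele 2 in row 2) is tested for
non-randomness.  In a panel of inbred lines, depths of the two alleles of
a real variant concentrate in roughly disjoint taxon subsets; random
scatter indicates sequencing/alignment error.  Because the chi-square
approximation is a de-facto lower bound on the exact P-value in the
non-significant regime, the cheap chi-square test is run first and the
expensive Monte-Carlo Fisher exact test (fixed-margin table sampling, as
in R's simulated ``fisher.test``) only when chi-square P < 0.2.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats
from scipy.special import gammaln

DEFAULT_ALPHA = 0.01
DEFAULT_CHISQ_GATE = 0.2
DEFAULT_REPLICATES = 2000


def _rng_for_site(seed: int, chrom: str, pos: int) -> np.random.Generator:
    """Per-site RNG stream, reproducible and independent of processing order."""
    key = zlib.crc32(chrom.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(pos)]))


def table_log_prob(table: np.ndarray) -> float:
    """Log-probability of a 2 × N table under fixed row and column margins
    (multivariate hypergeometric null)."""
    table = np.asarray(table, dtype=np.int64)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def seg_pvalue(
    table,
    replicates: int = DEFAULT_REPLICATES,
    seed=0,
    chisq_gate: float = DEFAULT_CHISQ_GATE,
) -> float:
    """Segregation-test P-value for a 2 × N allelic depth table.

    Columns (taxa) with zero total depth are dropped.  If either row sums
    to zero the table is degenerate and P = 1.  Otherwise the Pearson
    chi-square P-value (df = columns − 1, no continuity correction) is
    returned when it is >= *chisq_gate*; below the gate, a Monte-Carlo
    Fisher exact P-value is computed by sampling *replicates* tables with
    the observed margins (Patefield algorithm) and scoring
    ``P = (1 + #{log-prob(sim) <= log-prob(obs)}) / (replicates + 1)``.

    Parameters
    ----------
    table : array-like, shape (2, N)
    seed : int or numpy.random.Generator
        Seed (or ready generator) for the Monte-Carlo stage; the result is
        deterministic given the seed.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x N table")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or np.any(t.sum(axis=1) == 0):
        return 1.0

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = t.shape[1] - 1
    chi_p = float(stats.chi2.sf(chi2, df))
    if chi_p >= chisq_gate:
        return chi_p

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    sims = dist.rvs(replicates, method="patefield", random_state=rng)
    obs_lp = table_log_prob(t)
    sim_lp = (
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1)
        - gammaln(sims + 1).sum(axis=(1, 2))
    )
    hits = int(np.sum(sim_lp <= obs_lp + 1e-9))
    return (1 + hits) / (replicates + 1)


def st_filter(
    site,
    alpha: float = DEFAULT_ALPHA,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    chisq_gate: float = DEFAULT_CHISQ_GATE,
) -> tuple[list[str], float]:
    """Segregation-test filter for one tentative site.

    For every pair of site alleles, the 2 × N depth table across taxa is
    tested; an alternative allele survives iff the minimum P-value over
    the tables involving it is <= *alpha*.  Returns
    ``(kept_alt_alleles, min_pvalue)`` where *min_pvalue* is the smallest
    P-value over all tables at the site (recorded as the PV annotation).
    An empty kept list means the site is skipped.
    """
    alleles = site.alleles
    n_all = len(alleles)
    rng = _rng_for_site(seed, site.chrom, site.pos)
    best_for_allele = np.ones(n_all)
    overall = 1.0
    for i in range(n_all):
        for j in range(i + 1, n_all):
            table = np.stack([site.allele_depths[:, i], site.allele_depths[:, j]])
            p = seg_pvalue(table, replicates=replicates, seed=rng, chisq_gate=chisq_gate)
            best_for_allele[i] = min(best_for_allele[i], p)
            best_for_allele[j] = min(best_for_allele[j], p)
            overall = min(overall, p)
    kept = [alleles[k] for k in range(1, n_all) if best_for_allele[k] <= alpha]
    return kept, overall
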