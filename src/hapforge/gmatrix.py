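"""Helpers for diploid genotype matrices coded as unordered allele pairs.

A genotype matrix is an int8 array of shape ``(n_sites, n_taxa, 2)``
holding sorted allele indices (into each site's allele list: 0 = ref,
1 = first alt, ...) with ``-1`` in both slots for missing.
"""

from __future__ import annotations

import numpy as np

MISSING_PAIR = (-1, -1)


def is_missing(g: np.ndarray) -> np.ndarray:
    """Boolean mask of missing genotypes for a (..., 2) pair array."""
    return np.asarray(g)[..., 0] < 0


def is_het(g: np.ndarray) -> np.ndarray:
    """Boolean mask of heterozygous genotypes (missing entries are False)."""
    g = np.asarray(g)
    return (g[..., 0] >= 0) & (g[..., 0] != g[..., 1])


def allele_counts(g: np.ndarray, n_alleles: int) -> np.ndarray:
    """Per-genotype one-hot-ish allele counts, shape (..., n_alleles).

    Each genotype contributes its two allele copies; missing genotypes
    contribute nothing.
    """
    g = np.asarray(g)
    out = np.zeros(g.shape[:-1] + (n_alleles,), dtype=np.int64)
    for slot in (0, 1):
        a = g[..., slot]
        valid = a >= 0
        np.add.at(out, (*np.nonzero(valid), a[valid]), 1)
    return out


def shared_allele_counts(g1: np.ndarray, g2: np.ndarray, n_alleles: int = 6) -> np.ndarray:
    """Number of shared allele copies (0, 1, or 2) between genotype pairs.

    The multiset intersection size of the two allele pairs; the standard
    IBS sharing count.  Entries where either genotype is missing are -1.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    c1 = allele_counts(g1, n_alleles)
    c2 = allele_counts(g2, n_alleles)
    shared = np.minimum(c1, c2).sum(axis=-1)
    miss = is_missing(g1) | is_missing(g2)
    return np.where(miss, -1, shared)


def ibs_mismatch(g1: np.ndarray, g2: np.ndarray, n_alleles: int = 6) -> np.ndarray:
    """Per-site IBS mismatch: 0 identical, 0.5 het-vs-hom overlap, 1 disjoint.

    ``nan`` where either genotype is missing.
    """
    shared = shared_allele_counts(g1, g2, n_alleles)
    out = 1.0 - shared / 2.0
    return np.where(shared < 0, np.nan, out)


def genotype_class(g: np.ndarray, major_allele: np.ndarray) -> np.ndarray:
    """Classify genotypes: 0 major-hom, 1 het, 2 minor-hom, -1 missing.

    *major_allele* is the per-site major allele index, broadcast against
    the site axis of *g* (shape (n_sites, n_taxa, 2)).
    """
    g = np.asarray(g)
    maj = np.asarray(major_allele)[:, None]
    miss = is_missing(g)
    het = is_het(g)
    major_hom = (~het) & (g[..., 0] == maj)
    out = np.full(g.shape[:-1], 2, dtype=np.int8)
    out[het] = 1
    out[major_hom] = 0
    out[miss] = -1
    return out
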