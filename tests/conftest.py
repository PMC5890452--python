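from __future__ import annotations

import numpy as np
import pytest

from hapforge.genotyper import TentativeSite


def make_site(
    genotypes,
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alts=("C",),
    allele_depths=None,
    quals=None,
):
    """Build a TentativeSite from a list of site-allele pairs.

    *genotypes*: iterable of (a0, a1) pairs over site-allele indices, or
    None for missing.
    """
    gt = np.array(
        [(-1, -1) if g is None else (min(g), max(g)) for g in genotypes], dtype=np.int8
    )
    n_taxa = len(gt)
    n_alleles = 1 + len(alts)
    if allele_depths is None:
        allele_depths = np.zeros((n_taxa, n_alleles), dtype=np.int64)
        for t in range(n_taxa):
            if gt[t, 0] >= 0:
                allele_depths[t, gt[t, 0]] += 5
                allele_depths[t, gt[t, 1]] += 5
    if quals is None:
        quals = np.full(n_alleles, 35, dtype=np.int64)
    return TentativeSite(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_alleles=list(alts),
        genotypes=gt,
        allele_depths=np.asarray(allele_depths, dtype=np.int64),
        mean_quals=np.asarray(quals, dtype=np.int64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
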