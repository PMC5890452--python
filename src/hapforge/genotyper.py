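"""Likelihood genotype calling and tentative-site discovery.

Genotypes are called per taxon from the 6-allele depth vector under a
multinomial read model with a uniform error rate ``eps`` (default 1%):

* homozygote ``aa``:  P(read = a) = 1 - eps, any other allele eps/5;
* heterozygote ``ab``: P(read in {a, b}) = (1 - eps)/2 + eps/10 each,
  any other allele eps/5.

The maximum-likelihood unordered pair over the 21 possible genotypes is
returned; a taxon with zero total depth is missing.  Site discovery then
keeps positions where at least 10 taxa have coverage, a non-reference
allele is observed in the reads, and not every called genotype is a
reference homozygote; up to the 2 most abundant alternative alleles (by
summed read depth) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .alleles import ALLELES, N_ALLELES, allele_index

#: Sentinel for a missing genotype call.
MISSING = -1

#: The 21 unordered allele pairs (i <= j) of the 6-allele space, in
#: lexicographic order.  Genotype calls index into this list.
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    combinations_with_replacement(range(N_ALLELES), 2)
)
_PAIR_INDEX = {p: k for k, p in enumerate(GENOTYPE_PAIRS)}


def _log_emission_matrix(error_rate: float) -> np.ndarray:
    """21 × 6 matrix of log per-read emission probabilities."""
    logp = np.empty((len(GENOTYPE_PAIRS), N_ALLELES))
    for k, (a, b) in enumerate(GENOTYPE_PAIRS):
        row = np.full(N_ALLELES, error_rate / 5.0)
        if a == b:
            row[a] = 1.0 - error_rate
        else:
            row[a] = row[b] = (1.0 - error_rate) / 2.0 + error_rate / 10.0
        logp[k] = np.log(row)
    return logp


def call_genotypes(depths: np.ndarray, error_rate: float = 0.01) -> np.ndarray:
    """Maximum-likelihood genotype calls for a block of depth vectors.

    Parameters
    ----------
    depths : ndarray, shape (..., 6)
        Per-allele read counts.
    error_rate : float
        Uniform per-read error rate, in (0, 0.5).

    Returns
    -------
    ndarray of int, shape ``depths.shape[:-1]``
        Index into :data:`GENOTYPE_PAIRS`, or :data:`MISSING` where total
        depth is zero.  Likelihood ties break toward the homozygote of the
        highest-depth allele, then lexicographic pair order.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    depths = np.asarray(depths, dtype=np.float64)
    if depths.shape[-1] != N_ALLELES:
        raise ValueError("last axis must have length 6")
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    logp = _log_emission_matrix(error_rate)
    # log-likelihood of each of the 21 genotypes, up to the multinomial
    # coefficient (constant across genotypes)
    ll = depths @ logp.T  # (..., 21)
    calls = np.argmax(ll, axis=-1)
    best = np.take_along_axis(ll, calls[..., None], axis=-1)[..., 0]
    # deterministic tie-break
    tied = (ll >= best[..., None] - 1e-9).sum(axis=-1) > 1
    if np.any(tied):
        flat_d = depths.reshape(-1, N_ALLELES)
        flat_ll = ll.reshape(-1, len(GENOTYPE_PAIRS))
        flat_calls = calls.reshape(-1)
        for idx in np.nonzero(tied.reshape(-1))[0]:
            row = flat_ll[idx]
            cand = np.nonzero(row >= row.max() - 1e-9)[0]
            top = int(np.argmax(flat_d[idx]))  # highest-depth allele
            hom = _PAIR_INDEX[(top, top)]
            flat_calls[idx] = hom if hom in cand else int(cand[0])
        calls = flat_calls.reshape(calls.shape)
    calls = np.where(depths.sum(axis=-1) > 0, calls, MISSING)
    return calls


def call_genotype(depths, error_rate: float = 0.01) -> tuple[int, int] | None:
    """Call a single taxon's genotype from its 6-allele depth vector.

    Returns the unordered allele-index pair, or ``None`` (missing) when
    all depths are zero.
    """
    k = int(call_genotypes(np.asarray(depths, dtype=np.int64), error_rate))
    return None if k == MISSING else GENOTYPE_PAIRS[k]


@dataclass
class TentativeSite:
    """One candidate variant site emerging from discovery.

    ``genotypes`` holds per-taxon unordered pairs of *site-allele*
    indices (0 = ref, 1 = first alt, 2 = second alt), with (-1, -1) for
    missing.  ``allele_depths`` is the per-taxon depth over site alleles.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: np.ndarray  # (n_taxa, 2) int8, site-allele indices, -1 missing
    allele_depths: np.ndarray  # (n_taxa, n_site_alleles) int64
    mean_quals: np.ndarray  # (n_site_alleles,) depth-weighted mean quality
    info: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    @property
    def n_taxa(self) -> int:
        return self.genotypes.shape[0]

    def minor_depths(self, alt_index: int) -> np.ndarray:
        """Per-taxon read depth of the given alternative allele (1-based
        into ``alt_alleles`` is ``alt_index + 1`` in site-allele space)."""
        return self.allele_depths[:, alt_index + 1]

    def is_indel(self) -> bool:
        return any(a in ("I", "D") for a in self.alleles)


def discover_site(
    chrom: str,
    pos: int,
    depths: np.ndarray,
    quals: np.ndarray,
    ref_allele: str,
    min_covered_taxa: int = 10,
    error_rate: float = 0.01,
) -> TentativeSite | None:
    """Screen one genomic position for tentative variation.

    Parameters
    ----------
    depths, quals : ndarray, shape (n_taxa, 6)
        Per-taxon allelic depths and mean base qualities.
    ref_allele : str
        Reference allele symbol (A/C/G/T).

    Returns
    -------
    TentativeSite or None
        ``None`` when fewer than *min_covered_taxa* taxa have coverage,
        when no non-reference allele appears in the reads, or when every
        called genotype is a reference homozygote.  Otherwise the site
        with alternative alleles sorted by summed read depth and truncated
        to the 2 most abundant; genotypes carrying a pruned allele are set
        to missing.
    """
    ref_idx = allele_index(ref_allele)
    depths = np.asarray(depths, dtype=np.int64)
    quals = np.asarray(quals, dtype=np.int64)
    covered = depths.sum(axis=1) > 0
    if covered.sum() < min_covered_taxa:
        return None
    total_per_allele = depths.sum(axis=0)
    if (total_per_allele.sum() - total_per_allele[ref_idx]) == 0:
        return None

    calls = call_genotypes(depths, error_rate)
    pairs = np.array(GENOTYPE_PAIRS, dtype=np.int64)
    called = calls != MISSING
    if not called.any():
        return None
    gt = np.full((depths.shape[0], 2), -1, dtype=np.int64)
    gt[called] = pairs[calls[called]]
    # all non-missing calls reference homozygous -> skip
    if np.all((gt[called] == ref_idx).all(axis=1)):
        return None

    # alternative alleles present in called genotypes, ranked by total depth
    present = np.zeros(N_ALLELES, dtype=bool)
    present[gt[called].ravel()] = True
    present[ref_idx] = False
    alt_candidates = np.nonzero(present)[0]
    if len(alt_candidates) == 0:
        return None
    order = sorted(alt_candidates, key=lambda a: (-total_per_allele[a], a))
    alts = order[:2]

    site_alleles = [ref_idx, *alts]
    remap = np.full(N_ALLELES, -1, dtype=np.int64)
    for s, a in enumerate(site_alleles):
        remap[a] = s
    site_gt = np.full_like(gt, -1)
    ok = called & np.all(np.isin(gt, site_alleles), axis=1)
    site_gt[ok] = remap[gt[ok]]
    site_gt = np.sort(site_gt, axis=1)
    site_gt[~ok] = -1

    ok2 = site_gt[:, 0] >= 0
    if not np.any(site_gt[ok2] > 0):
        return None  # pruning left only reference homozygotes

    allele_depths = depths[:, site_alleles]
    dsum = allele_depths.sum(axis=0)
    qsum = (quals[:, site_alleles] * depths[:, site_alleles]).sum(axis=0)
    mean_quals = np.rint(np.divide(qsum, dsum, out=np.zeros_like(qsum, dtype=float), where=dsum > 0))
    return TentativeSite(
        chrom=chrom,
        pos=int(pos),
        ref_allele=ALLELES[ref_idx],
        alt_alleles=[ALLELES[a] for a in alts],
        genotypes=site_gt.astype(np.int8),
        allele_depths=allele_depths,
        mean_quals=mean_quals.astype(np.int64),
    )


def minor_depth_filter(site: TentativeSite) -> list[str]:
    """Apply the ">1, >2" minor-allele read-support filter.

    An alternative allele is kept iff its read support is greater than 1
    in at least one taxon *and* greater than 2 summed across all taxa.
    Returns the surviving alternative alleles (empty list = site fails).
    """
    kept = []
    for k, alt in enumerate(site.alt_alleles):
        d = site.minor_depths(k)
        if d.max(initial=0) > 1 and d.sum() > 2:
            kept.append(alt)
    return kept
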