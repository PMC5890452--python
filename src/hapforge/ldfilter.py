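"""Linkage-disequilibrium filter against the anchor map.

Any real variant should be in strong *local* LD with nearby trusted
markers.  Each candidate site is tested against anchor sites using the
two-sided Fisher exact P-value of the 2 × 2 haplotype-count table
(AB/Ab/aB/ab), where heterozygous genotypes count as minor-allele
homozygotes so each taxon contributes at most one haplotype.  Up to the
20 best hits are collected; the site is rejected when the best hit is
weak (P > 1e-6) or when no collected hit is local (same chromosome,
within 1 Mb, P < 10 × best P).  Sites for which no anchor pair is
testable pass unassessed (no LLD flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .gmatrix import is_het, is_missing
from .ibd import AnchorMap

DEFAULT_MIN_BP = 2500
DEFAULT_MIN_TAXA = 40
DEFAULT_MIN_MINOR = 2
DEFAULT_MAX_HITS = 20
DEFAULT_BEST_P_MAX = 1e-6
DEFAULT_LOCAL_RADIUS = 1_000_000
DEFAULT_LOCAL_FACTOR = 10.0

#: sentinel for pairs failing the testability conditions
UNTESTABLE = None

#: ld_filter verdicts
PASS_LLD = "lld"
PASS_UNASSESSED = "unassessed"
REJECT = "reject"


@dataclass
class LDHit:
    """One tested candidate/anchor pair."""

    anchor_chrom: str
    anchor_pos: int
    pvalue: float

    def is_local(self, chrom: str, pos: int, radius: float) -> bool:
        return self.anchor_chrom == chrom and abs(self.anchor_pos - pos) <= radius


def _minor_haplotypes(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse genotypes to per-taxon haplotypes: 1 = carries a minor
    (non-major) allele (hets count as minor homozygotes), 0 = major.

    Returns (haplotype, nonmissing-mask)."""
    g = np.asarray(genotypes)
    nonmiss = ~is_missing(g)
    if nonmiss.sum() == 0:
        return np.zeros(g.shape[0], dtype=np.int8), nonmiss
    counts = np.bincount(g[nonmiss].ravel(), minlength=6)
    major = int(np.argmax(counts))
    minor = nonmiss & (is_het(g) | (g[..., 0] != major))
    return minor.astype(np.int8), nonmiss


def fisher_exact_2x2(n11, n12, n21, n22):
    """Two-sided Fisher exact P (point-probability method) for 2 × 2 tables.

    Vectorized over array inputs via the hypergeometric distribution; sums
    the probabilities of all tables with the observed margins whose point
    probability does not exceed the observed one (with a small relative
    tolerance against floating-point ties, matching the R convention).
    """
    n11, n12, n21, n22 = np.broadcast_arrays(
        *[np.asarray(x, dtype=np.int64) for x in (n11, n12, n21, n22)]
    )
    shape = n11.shape
    r1 = n11 + n12
    c1 = n11 + n21
    n = n11 + n12 + n21 + n22
    lo = np.maximum(0, r1 + c1 - n)
    hi = np.minimum(r1, c1)
    width = int((hi - lo).max(initial=0)) + 1
    k = lo[..., None] + np.arange(width)
    valid = k <= hi[..., None]
    kk = np.where(valid, k, lo[..., None])

    def _logpmf(x):
        return (
            gammaln(r1 + 1)[..., None]
            + gammaln(n - r1 + 1)[..., None]
            - gammaln(n + 1)[..., None]
            + gammaln(c1 + 1)[..., None]
            + gammaln(n - c1 + 1)[..., None]
            - gammaln(x + 1)
            - gammaln(r1[..., None] - x + 1)
            - gammaln(c1[..., None] - x + 1)
            - gammaln(n[..., None] - r1[..., None] - c1[..., None] + x + 1)
        )

    logpmf = np.where(valid, _logpmf(kk), -np.inf)
    obs = _logpmf(n11[..., None])[..., 0]
    include = logpmf <= obs[..., None] + 1e-7
    p = np.exp(logpmf, where=include & np.isfinite(logpmf), out=np.zeros_like(logpmf)).sum(axis=-1)
    p = np.minimum(p, 1.0)
    return p.reshape(shape) if shape else float(p)


def ld_pvalue(
    g_a: np.ndarray,
    g_b: np.ndarray,
    pos_a: tuple[str, int],
    pos_b: tuple[str, int],
    min_bp: int = DEFAULT_MIN_BP,
    min_taxa: int = DEFAULT_MIN_TAXA,
    min_minor: int = DEFAULT_MIN_MINOR,
):
    """Fisher exact LD P-value for one candidate/anchor site pair.

    Returns ``None`` (UNTESTABLE) unless (i) the sites are at least
    *min_bp* apart (different chromosomes always qualify), (ii) at least
    *min_taxa* taxa are nonmissing at both sites, and (iii) at least
    *min_minor* taxa carry minor alleles at each site among those taxa.
    """
    chrom_a, p_a = pos_a
    chrom_b, p_b = pos_b
    if chrom_a == chrom_b and abs(p_a - p_b) < min_bp:
        return UNTESTABLE
    hap_a, nm_a = _minor_haplotypes(g_a)
    hap_b, nm_b = _minor_haplotypes(g_b)
    both = nm_a & nm_b
    if both.sum() < min_taxa:
        return UNTESTABLE
    a = hap_a[both].astype(bool)
    b = hap_b[both].astype(bool)
    if a.sum() < min_minor or b.sum() < min_minor:
        return UNTESTABLE
    n11 = int(np.sum(a & b))
    n12 = int(np.sum(a & ~b))
    n21 = int(np.sum(~a & b))
    n22 = int(np.sum(~a & ~b))
    return float(fisher_exact_2x2(n11, n12, n21, n22))


def ld_filter(
    site,
    anchor: AnchorMap,
    max_hits: int = DEFAULT_MAX_HITS,
    best_p_max: float = DEFAULT_BEST_P_MAX,
    local_radius: float = DEFAULT_LOCAL_RADIUS,
    local_factor: float = DEFAULT_LOCAL_FACTOR,
    min_bp: int = DEFAULT_MIN_BP,
    min_taxa: int = DEFAULT_MIN_TAXA,
    min_minor: int = DEFAULT_MIN_MINOR,
) -> tuple[str, list[LDHit]]:
    """Run the LD filter for one tentative site against the whole anchor.

    Returns ``(verdict, hits)`` where *verdict* is one of
    :data:`PASS_LLD`, :data:`PASS_UNASSESSED`, :data:`REJECT` and *hits*
    is the collected best-hit list (up to *max_hits*, ordered by
    (P, chrom, pos)).
    """
    hap_s, nm_s = _minor_haplotypes(site.genotypes)
    hits: list[LDHit] = []

    # vectorized testability + haplotype table counts over all anchor sites
    g = anchor.genotypes
    nm = ~is_missing(g)
    # per-anchor-site minor haplotypes (biallelic anchor: major computed per site)
    het = is_het(g)
    with np.errstate(invalid="ignore"):
        alt_cnt = ((g[..., 0] > 0).astype(np.int64) + (g[..., 1] > 0).astype(np.int64)) * nm
        n_nm = nm.sum(axis=1)
        alt_total = alt_cnt.sum(axis=1)
        major_is_alt = alt_total > n_nm  # more alt copies than ref copies
    minor = nm & np.where(
        major_is_alt[:, None], (g[..., 0] == 0) | het, (g[..., 0] > 0) | (g[..., 1] > 0)
    )

    same_chrom = anchor.chroms == site.chrom
    far_enough = ~same_chrom | (np.abs(anchor.positions - site.pos) >= min_bp)
    both = nm & nm_s[None, :].astype(bool)
    n_both = both.sum(axis=1)
    s_minor = both & hap_s[None, :].astype(bool)
    a_minor = both & minor
    testable = (
        far_enough
        & (n_both >= min_taxa)
        & (s_minor.sum(axis=1) >= min_minor)
        & (a_minor.sum(axis=1) >= min_minor)
    )
    if not np.any(testable):
        return PASS_UNASSESSED, hits

    idx = np.nonzero(testable)[0]
    n11 = (s_minor[idx] & a_minor[idx]).sum(axis=1)
    n12 = (s_minor[idx] & ~a_minor[idx] & both[idx]).sum(axis=1)
    n21 = (~s_minor[idx] & a_minor[idx] & both[idx]).sum(axis=1)
    n22 = (~s_minor[idx] & ~a_minor[idx] & both[idx]).sum(axis=1)
    pvals = fisher_exact_2x2(n11, n12, n21, n22)

    # ties in P are broken by proximity to the candidate site, so that a
    # local hit among equally strong ones is never crowded out of the list
    def _tie_key(k):
        a_chrom = str(anchor.chroms[idx[k]])
        a_pos = int(anchor.positions[idx[k]])
        dist = abs(a_pos - site.pos) if a_chrom == site.chrom else np.inf
        return (pvals[k], dist, a_chrom, a_pos)

    order = sorted(range(len(idx)), key=_tie_key)[:max_hits]
    hits = [
        LDHit(str(anchor.chroms[idx[k]]), int(anchor.positions[idx[k]]), float(pvals[k]))
        for k in order
    ]
    best_p = hits[0].pvalue
    if best_p > best_p_max:
        return REJECT, hits
    for h in hits:
        if h.is_local(site.chrom, site.pos, local_radius) and h.pvalue < local_factor * best_p:
            return PASS_LLD, hits
    return REJECT, hits
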