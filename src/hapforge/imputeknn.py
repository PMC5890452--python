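"""LD-KNN genotype imputation and self-imputation accuracy statistics.

For each target site a list of up to 70 surrounding sites in best LD
(r² of numerically coded genotypes) within ±600 kb is compiled, keeping
only sites with heterozygosity < 3% and more than 50% nonmissing taxa.
For each target taxon, up to 30 nearest-neighbour taxa are selected by
IBS distance over those LD sites (neighbours must be nonmissing at the
target site, have at least 10 common LD sites, at most 50% missing LD
genotypes, and distance <= 0.1).  Each candidate genotype g receives the
weight

    w_g = sum_i 1 / (1 + 70 * d_i)

over neighbours i carrying g; the top genotype is imputed when its
weight is at least 10 times the runner-up's, else the imputation is
inconclusive (UNKNOWN).  In the output only originally missing
genotypes are updated; every genotype is nevertheless test-imputed to
build the transition matrix (original class × imputed class) and the
per-site ImpHomoAccuracy / ImpMinorAccuracy statistics.  Inconclusive
imputations of missing entries at sites with pre-imputation MAF < 1%
become major-allele homozygotes in the output.  The procedure is fully
deterministic: no randomness, ties broken by genotype code and taxon
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmatrix import genotype_class, is_het, is_missing

DEFAULT_WINDOW_BP = 600_000
DEFAULT_MAX_LD_SITES = 70
DEFAULT_HET_MAX = 0.03
DEFAULT_PRESENCE_MIN = 0.5
DEFAULT_MAX_D = 0.1
DEFAULT_MIN_COMMON = 10
DEFAULT_MAX_MISSING = 0.5
DEFAULT_K = 30
DEFAULT_WEIGHT_SCALE = 70.0
DEFAULT_DOMINANCE = 10.0
DEFAULT_MAF_FALLBACK = 0.01

#: vote outcome when no genotype dominates (or no neighbours exist)
UNKNOWN = None

#: transition-matrix classes, in row/column order (rows exclude "unknown")
TRANSITION_CLASSES = ("major_hom", "het", "minor_hom", "indel", "unknown")


def _pair_codes(g: np.ndarray) -> np.ndarray:
    """Pack sorted allele pairs into one small int in [0, 63]; missing -> -1."""
    g = np.asarray(g)
    code = g[..., 0].astype(np.int16) * 8 + g[..., 1]
    return np.where(g[..., 0] < 0, -1, code).astype(np.int16)


def _build_mismatch_lut() -> np.ndarray:
    """64 x 64 IBS mismatch table between pair codes (alleles 0..7)."""
    codes = np.arange(64)
    a0, a1 = codes // 8, codes % 8
    tab = np.empty((64, 64))
    for c in codes:
        s = np.zeros(64, dtype=int)
        for allele in {int(a0[c]), int(a1[c])}:
            have_c = int(a0[c] == allele) + int(a1[c] == allele)
            have = (a0 == allele).astype(int) + (a1 == allele).astype(int)
            s += np.minimum(have, have_c)
        tab[c] = 1.0 - s / 2.0
    return tab


_MISMATCH_LUT = _build_mismatch_lut()


@dataclass
class LDSiteList:
    """Sites in best LD with a target site."""

    target: int
    sites: np.ndarray  # indices into the site axis, best r2 first
    r2: np.ndarray


@dataclass
class NeighborSet:
    """Nearest neighbours of one taxon at one target site."""

    taxon: int
    neighbors: np.ndarray  # taxon indices
    distances: np.ndarray


@dataclass
class ImputationResult:
    """Output of :func:`impute_matrix`."""

    genotypes: np.ndarray  # (n_sites, n_taxa, 2) with missing entries filled
    transition: np.ndarray  # (4, 5) counts: original class x imputed class
    imp_homo_accuracy: np.ndarray  # per site, nan when undefined
    imp_minor_accuracy: np.ndarray
    maf0: np.ndarray  # pre-imputation MAF per site
    test_imputed: np.ndarray  # (n_sites, n_taxa) pair-code of test imputation, -1 unknown

    @property
    def transition_classes(self):
        return TRANSITION_CLASSES


def _major_alleles(g: np.ndarray, n_alleles: int = 8) -> np.ndarray:
    """Per-site major allele index (most allele copies among nonmissing)."""
    counts = np.zeros((g.shape[0], n_alleles), dtype=np.int64)
    for slot in (0, 1):
        a = g[..., slot]
        rows, cols = np.nonzero(a >= 0)
        np.add.at(counts, (rows, a[rows, cols].astype(np.int64)), 1)
    return np.argmax(counts, axis=1)


def _dosage(g: np.ndarray, major: np.ndarray) -> np.ndarray:
    """Numeric genotype coding: 0 major hom, 0.5 het, 1 minor hom; nan missing."""
    cls = genotype_class(g, major)
    return np.where(cls < 0, np.nan, cls / 2.0)


def _maf(g: np.ndarray, major: np.ndarray) -> np.ndarray:
    """Per-site frequency of non-major allele copies among nonmissing."""
    n_copies = 2 * (~is_missing(g)).sum(axis=1)
    minor_copies = np.zeros(g.shape[0], dtype=np.int64)
    for slot in (0, 1):
        a = g[..., slot]
        minor_copies += ((a >= 0) & (a != np.asarray(major)[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_copies > 0, minor_copies / np.maximum(n_copies, 1), 0.0)


def select_ld_sites(
    target: int,
    genotypes: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_sites: int = DEFAULT_MAX_LD_SITES,
    het_max: float = DEFAULT_HET_MAX,
    presence_min: float = DEFAULT_PRESENCE_MIN,
    major: np.ndarray | None = None,
) -> LDSiteList:
    """Compile the LD-site list for one target site.

    Candidates are all other sites on the same chromosome within
    ±*window_bp*, with heterozygosity < *het_max* and more than
    *presence_min* of taxa nonmissing; the *max_sites* highest-r²
    candidates are kept (r² = squared Pearson correlation of the
    0/0.5/1 genotype coding over taxa nonmissing at both sites; pairs
    with fewer than 2 informative taxa or zero variance score 0).
    Ties break by site order.
    """
    g = np.asarray(genotypes)
    n_sites, n_taxa = g.shape[:2]
    positions = np.asarray(positions)
    chroms = np.asarray(chroms, dtype=object)
    if major is None:
        major = _major_alleles(g)
    near = (
        (chroms == chroms[target])
        & (np.abs(positions - positions[target]) <= window_bp)
        & (np.arange(n_sites) != target)
    )
    cand = np.nonzero(near)[0]
    if len(cand) == 0:
        return LDSiteList(target, np.empty(0, dtype=int), np.empty(0))
    nm = ~is_missing(g[cand])
    het = is_het(g[cand])
    n_nm = nm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(n_nm > 0, het.sum(axis=1) / np.maximum(n_nm, 1), 1.0)
    ok = (n_nm > presence_min * n_taxa) & (het_frac < het_max)
    cand = cand[ok]
    if len(cand) == 0:
        return LDSiteList(target, np.empty(0, dtype=int), np.empty(0))

    x = _dosage(g[target : target + 1], np.asarray(major)[target : target + 1])[0]
    y = _dosage(g[cand], np.asarray(major)[cand])  # (n_cand, n_taxa)
    both = np.isfinite(x)[None, :] & np.isfinite(y)
    xm = np.where(both, x[None, :], 0.0)
    ym = np.where(both, y, 0.0)
    n = both.sum(axis=1)
    sx = xm.sum(axis=1)
    sy = ym.sum(axis=1)
    sxx = (xm * xm).sum(axis=1)
    syy = (ym * ym).sum(axis=1)
    sxy = (xm * ym).sum(axis=1)
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((n >= 2) & (den > 0), num * num / den, 0.0)
    order = np.lexsort((cand, -r2))[:max_sites]
    return LDSiteList(target, cand[order], r2[order])


def _ld_distance_matrix(codes: np.ndarray):
    """All-pairs mean IBS mismatch and comparable-site counts over LD sites.

    *codes* is the (n_ld, n_taxa) pair-code matrix; returns (D, C) where
    ``D[i, j]`` is the mean mismatch over sites where both are nonmissing
    and ``C[i, j]`` the number of such sites.
    """
    n_ld, n_taxa = codes.shape
    miss = codes < 0
    safe = np.where(miss, 0, codes)
    D = np.zeros((n_taxa, n_taxa))
    C = np.zeros((n_taxa, n_taxa), dtype=np.int64)
    for i in range(n_taxa):
        comparable = ~miss[:, i : i + 1] & ~miss
        mm = np.where(comparable, _MISMATCH_LUT[safe[:, i : i + 1], safe], 0.0)
        C[i] = comparable.sum(axis=0)
        with np.errstate(invalid="ignore"):
            D[i] = mm.sum(axis=0) / np.maximum(C[i], 1)
    return D, C


def neighbor_distances(
    target_taxon: int,
    ld_sites: LDSiteList,
    genotypes: np.ndarray,
    target_site: int,
    max_d: float = DEFAULT_MAX_D,
    min_common: int = DEFAULT_MIN_COMMON,
    max_missing: float = DEFAULT_MAX_MISSING,
    k: int = DEFAULT_K,
) -> NeighborSet:
    """Select up to *k* nearest-neighbour taxa for one target taxon.

    Distances are mean IBS mismatch over LD sites comparable between the
    two taxa.  Excluded: the target itself, taxa missing at the target
    site, taxa with more than *max_missing* missing LD genotypes, fewer
    than *min_common* common LD sites, or distance > *max_d*.  Ties break
    by taxon order.
    """
    g = np.asarray(genotypes)
    if len(ld_sites.sites) == 0:
        return NeighborSet(target_taxon, np.empty(0, dtype=int), np.empty(0))
    codes = _pair_codes(g[ld_sites.sites])
    miss = codes < 0
    safe = np.where(miss, 0, codes)
    comparable = ~miss[:, target_taxon : target_taxon + 1] & ~miss
    counts = comparable.sum(axis=0)
    mm = np.where(comparable, _MISMATCH_LUT[safe[:, target_taxon : target_taxon + 1], safe], 0.0)
    d = mm.sum(axis=0) / np.maximum(counts, 1)
    return _select_neighbors(
        target_taxon, d, counts, miss.mean(axis=0), ~is_missing(g[target_site]),
        max_d, min_common, max_missing, k,
    )


def _select_neighbors(
    target_taxon, d, counts, miss_frac, at_target, max_d, min_common, max_missing, k
) -> NeighborSet:
    n_taxa = len(d)
    eligible = (
        (np.arange(n_taxa) != target_taxon)
        & at_target
        & (miss_frac <= max_missing)
        & (counts >= min_common)
        & (d <= max_d)
    )
    idx = np.nonzero(eligible)[0]
    order = np.lexsort((idx, d[idx]))[:k]
    sel = idx[order]
    return NeighborSet(target_taxon, sel, d[sel])


def knn_vote(
    neighbors: NeighborSet,
    site_genotypes: np.ndarray,
    weight_scale: float = DEFAULT_WEIGHT_SCALE,
    dominance: float = DEFAULT_DOMINANCE,
):
    """Weighted genotype vote among nearest neighbours.

    Each neighbour with genotype g contributes ``1 / (1 + 70 d)`` to
    w_g.  The best genotype (sorted allele pair) is returned when
    ``w_best >= dominance * w_second`` (an absent runner-up counts as 0);
    otherwise :data:`UNKNOWN`.  Ties break by genotype code order.
    """
    if len(neighbors.neighbors) == 0:
        return UNKNOWN
    codes = _pair_codes(np.asarray(site_genotypes)[neighbors.neighbors])
    weights: dict[int, float] = {}
    for c, dist in zip(codes.tolist(), neighbors.distances.tolist()):
        weights[c] = weights.get(c, 0.0) + 1.0 / (1.0 + weight_scale * dist)
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    best_code, best_w = ranked[0]
    second_w = ranked[1][1] if len(ranked) > 1 else 0.0
    if second_w > 0 and best_w < dominance * second_w:
        return UNKNOWN
    return (best_code // 8, best_code % 8)


def impute_matrix(
    genotypes: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    indel_sites: np.ndarray | None = None,
    maf_fallback: float = DEFAULT_MAF_FALLBACK,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_ld_sites: int = DEFAULT_MAX_LD_SITES,
    het_max: float = DEFAULT_HET_MAX,
    presence_min: float = DEFAULT_PRESENCE_MIN,
    max_d: float = DEFAULT_MAX_D,
    min_common: int = DEFAULT_MIN_COMMON,
    max_missing: float = DEFAULT_MAX_MISSING,
    k: int = DEFAULT_K,
    weight_scale: float = DEFAULT_WEIGHT_SCALE,
    dominance: float = DEFAULT_DOMINANCE,
) -> ImputationResult:
    """Impute a genotype matrix site by site.

    Every genotype (missing or not) is test-imputed; the returned matrix
    updates only the originally missing entries.  Inconclusive (UNKNOWN)
    imputations of missing entries at sites with pre-imputation MAF <
    *maf_fallback* are set to the major-allele homozygote.

    Parameters
    ----------
    genotypes : ndarray (n_sites, n_taxa, 2)
        Sorted allele-index pairs, (-1, -1) missing.
    positions, chroms : ndarray (n_sites,)
    indel_sites : bool ndarray (n_sites,), optional
        Marks sites whose allele list contains I/D; nonmissing genotypes
        carrying a non-reference allele there are reported in the
        "indel" row/column of the transition matrix.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_taxa = g.shape[:2]
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    if indel_sites is None:
        indel_sites = np.zeros(n_sites, dtype=bool)

    major = _major_alleles(g)
    maf0 = _maf(g, major)
    cls = genotype_class(g, major)  # 0 major-hom, 1 het, 2 minor-hom, -1 missing

    out = g.copy()
    transition = np.zeros((4, 5), dtype=np.int64)
    imp_homo = np.full(n_sites, np.nan)
    imp_minor = np.full(n_sites, np.nan)
    test_imp = np.full((n_sites, n_taxa), -1, dtype=np.int16)

    for s in range(n_sites):
        lds = select_ld_sites(
            s, g, positions, chroms, window_bp, max_ld_sites, het_max, presence_min, major
        )
        site_g = g[s]
        at_target = ~is_missing(site_g)
        if len(lds.sites):
            codes = _pair_codes(g[lds.sites])
            D, C = _ld_distance_matrix(codes)
            miss_frac = (codes < 0).mean(axis=0)
        hom_total = hom_ok = 0
        min_total = min_ok = 0
        for t in range(n_taxa):
            if len(lds.sites):
                nbrs = _select_neighbors(
                    t, D[t], C[t], miss_frac, at_target, max_d, min_common, max_missing, k
                )
                vote = knn_vote(nbrs, site_g, weight_scale, dominance)
            else:
                vote = UNKNOWN
            orig_missing = site_g[t, 0] < 0
            if vote is not UNKNOWN:
                test_imp[s, t] = vote[0] * 8 + vote[1]
            if not orig_missing:
                # transition bookkeeping on originally nonmissing genotypes
                if indel_sites[s] and (site_g[t, 0] > 0 or site_g[t, 1] > 0):
                    row = 3
                else:
                    row = int(cls[s, t])
                if vote is UNKNOWN:
                    transition[row, 4] += 1
                    continue
                v0, v1 = vote
                v_het = v0 != v1
                if indel_sites[s] and (v0 > 0 or v1 > 0):
                    col = 3
                elif v_het:
                    col = 1
                else:
                    col = 0 if v0 == major[s] else 2
                transition[row, col] += 1
                if cls[s, t] in (0, 2):
                    hom_total += 1
                    hom_ok += int(not v_het)
                if cls[s, t] == 2:
                    min_total += 1
                    min_ok += int((not v_het) and v0 != major[s])
            else:
                if vote is not UNKNOWN:
                    out[s, t, 0] = min(vote)
                    out[s, t, 1] = max(vote)
                elif maf0[s] < maf_fallback:
                    out[s, t, 0] = out[s, t, 1] = major[s]
        if hom_total:
            imp_homo[s] = hom_ok / hom_total
        if min_total:
            imp_minor[s] = min_ok / min_total
    return ImputationResult(out, transition, imp_homo, imp_minor, maf0, test_imp)
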