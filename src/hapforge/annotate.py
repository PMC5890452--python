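"""Per-site and per-taxon summary statistics and the VCF flag set.

Site annotations: DP (total depth), NZ (called genotypes), AD (per-allele
depths), AC (alt allele counts), AQ (depth-weighted mean base quality),
GN (genotype-class counts), HT (heterozygote count), EF
(= het_frequency / (presence_frequency × MAF)), PV (segregation-test P),
MAF (non-major allele frequency summed over alternative alleles), MAF0
(pre-imputation MAF), FH (het fraction among the high-coverage taxon
subset).  Flags: FH2 (FH > 2%), DUP (het frequency > 3%), NI5 (indel or
within 5 bp of a putative indel), IBD1/LLD (from the IBD and LD
filters), INHMP311 (membership in the strictly filtered set).

Per-taxon quality is summarized by the inbreeding coefficient
F = (O − E) / (N − E) with E = Σ_k (1 − 2 p_k q_k) over the taxon's
genotyped sites, p_k the minor allele frequency at site k.
"""

from __future__ import annotations

import numpy as np

from .genotyper import TentativeSite
from .gmatrix import is_het, is_missing

FH2_THRESHOLD = 0.02
DUP_THRESHOLD = 0.03
NI5_RADIUS = 5


def site_allele_frequencies(site: TentativeSite) -> np.ndarray:
    """Allele frequencies from called genotypes (copies / 2·NZ)."""
    g = site.genotypes
    called = ~is_missing(g)
    n_alleles = len(site.alleles)
    counts = np.zeros(n_alleles, dtype=np.int64)
    for slot in (0, 1):
        a = g[called][:, slot]
        np.add.at(counts, a, 1)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def site_maf(site: TentativeSite) -> float:
    """Minor allele frequency: summed frequency of all non-major alleles."""
    freqs = site_allele_frequencies(site)
    if freqs.sum() == 0:
        return 0.0
    return float(freqs.sum() - freqs.max())


def genotype_number_vector(site: TentativeSite) -> np.ndarray:
    """GN vector: genotype-class counts in the order AA,AB,BB (1 alt) or
    AA,AB,AC,BB,BC,CC (2 alts), with A = ref, B/C = alts in ALT order."""
    n_alleles = len(site.alleles)
    pairs = [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]
    pairs.sort()  # (0,0),(0,1),(0,2),(1,1),(1,2),(2,2)
    index = {p: k for k, p in enumerate(pairs)}
    gn = np.zeros(len(pairs), dtype=np.int64)
    for t in range(site.n_taxa):
        a0, a1 = int(site.genotypes[t, 0]), int(site.genotypes[t, 1])
        if a0 >= 0:
            gn[index[(a0, a1)]] += 1
    return gn


def inbreeding_coefficient(taxon_genotypes: np.ndarray, maf: np.ndarray) -> float:
    """Per-taxon inbreeding coefficient F = (O − E)/(N − E).

    Parameters
    ----------
    taxon_genotypes : ndarray (n_sites, 2)
        The taxon's genotype pairs ((-1, -1) missing).
    maf : ndarray (n_sites,)
        Minor allele frequency p_k per site, computed from all taxa with
        nonmissing genotypes.

    O is the taxon's observed homozygote count, N its genotyped-site
    count and E = Σ_k (1 − 2 p_k q_k), q_k = 1 − p_k, summed over the
    genotyped sites.  Returns nan when N = E; raises on N = 0.
    """
    g = np.asarray(taxon_genotypes)
    maf = np.asarray(maf, dtype=float)
    called = ~is_missing(g)
    n = int(called.sum())
    if n == 0:
        raise ValueError("taxon has no genotyped sites")
    o = int((called & ~is_het(g)).sum())
    p = maf[called]
    e = float((1.0 - 2.0 * p * (1.0 - p)).sum())
    if np.isclose(n, e):
        return float("nan")
    return (o - e) / (n - e)


def high_coverage_subset(
    genotypes: np.ndarray, chroms: np.ndarray, designated_chrom: str, min_presence: float = 0.5
) -> np.ndarray:
    """Taxon mask: strictly more than *min_presence* nonmissing genotypes
    on the designated chromosome."""
    sel = np.asarray(chroms, dtype=object) == designated_chrom
    if sel.sum() == 0:
        return np.zeros(np.asarray(genotypes).shape[1], dtype=bool)
    nm = ~is_missing(np.asarray(genotypes)[sel])
    return nm.mean(axis=0) > min_presence


def fraction_het_highcov(site: TentativeSite, subset: np.ndarray) -> float:
    """FH: heterozygote fraction among nonmissing genotypes of the
    high-coverage subset at this site; nan when undefined."""
    subset = np.asarray(subset, dtype=bool)
    g = site.genotypes[subset]
    nm = ~is_missing(g)
    if nm.sum() == 0:
        return float("nan")
    return float(is_het(g)[nm].sum() / nm.sum())


def putative_indel_positions(sites: list[TentativeSite]) -> dict[str, np.ndarray]:
    """Positions (per chromosome) of sites whose alleles include I/D."""
    out: dict[str, list[int]] = {}
    for s in sites:
        if s.is_indel():
            out.setdefault(s.chrom, []).append(s.pos)
    return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in out.items()}


def near_indel(site: TentativeSite, indel_positions: dict[str, np.ndarray], radius: int = NI5_RADIUS) -> bool:
    """NI5 predicate: the site is an indel or lies within *radius* bp of a
    putative indel position."""
    if site.is_indel():
        return True
    pos = indel_positions.get(site.chrom)
    if pos is None or len(pos) == 0:
        return False
    i = np.searchsorted(pos, site.pos)
    for j in (i - 1, i):
        if 0 <= j < len(pos) and abs(int(pos[j]) - site.pos) <= radius:
            return True
    return False


def annotate_site(
    site: TentativeSite,
    highcov_subset: np.ndarray | None = None,
    indel_positions: dict[str, np.ndarray] | None = None,
    emit: tuple[str, ...] = ("DP", "NZ", "AD", "AC", "AQ", "GN", "HT", "EF", "MAF"),
    with_dup: bool = True,
) -> TentativeSite:
    """Compute the annotation set for one site in place (returns it).

    PV, MAF0, Imp*, IBD1, LLD, INHMP311 are attached by the pipeline
    stages that produce them; this function derives everything computable
    from depths and genotypes alone, plus FH/FH2 when a high-coverage
    subset is given and NI5/DUP when requested.
    """
    g = site.genotypes
    called = ~is_missing(g)
    nz = int(called.sum())
    gn = genotype_number_vector(site)
    ht = int(is_het(g)[called].sum())
    freqs = site_allele_frequencies(site)
    maf = site_maf(site)
    counts = np.zeros(len(site.alleles), dtype=np.int64)
    for slot in (0, 1):
        np.add.at(counts, g[called][:, slot], 1)

    info = site.info
    if "DP" in emit:
        info["DP"] = int(site.allele_depths.sum())
    if "NZ" in emit:
        info["NZ"] = nz
    if "AD" in emit:
        info["AD"] = [int(x) for x in site.allele_depths.sum(axis=0)]
    if "AC" in emit:
        info["AC"] = [int(x) for x in counts[1:]]
    if "AQ" in emit:
        info["AQ"] = [int(x) for x in site.mean_quals]
    if "GN" in emit:
        info["GN"] = [int(x) for x in gn]
    if "HT" in emit:
        info["HT"] = ht
    if "MAF" in emit:
        info["MAF"] = maf
    if "EF" in emit:
        presence = nz / site.n_taxa if site.n_taxa else 0.0
        het_freq = ht / nz if nz else 0.0
        info["EF"] = het_freq / (presence * maf) if presence > 0 and maf > 0 else float("nan")
    if highcov_subset is not None:
        fh = fraction_het_highcov(site, highcov_subset)
        info["FH"] = fh
        if np.isfinite(fh) and fh > FH2_THRESHOLD:
            site.flags.add("FH2")
    if indel_positions is not None and near_indel(site, indel_positions):
        site.flags.add("NI5")
    if with_dup and nz and is_het(g)[called].sum() / nz > DUP_THRESHOLD:
        site.flags.add("DUP")
    return site


def annotate_sites(
    sites: list[TentativeSite],
    designated_chrom: str | None = None,
    with_fh: bool = False,
    with_ni5: bool = True,
    with_dup: bool = True,
    **kwargs,
) -> list[TentativeSite]:
    """Annotate a list of sites.

    When *with_fh* is true, the high-coverage subset is determined once
    from the cohort (taxa with >50% nonmissing genotypes on
    *designated_chrom*, defaulting to the first chromosome present).
    """
    if not sites:
        return sites
    subset = None
    if with_fh:
        genotypes = np.stack([s.genotypes for s in sites])
        chroms = np.asarray([s.chrom for s in sites], dtype=object)
        if designated_chrom is None:
            designated_chrom = str(chroms[0])
        subset = high_coverage_subset(genotypes, chroms, designated_chrom)
    indel_pos = putative_indel_positions(sites) if with_ni5 else None
    for s in sites:
        annotate_site(s, highcov_subset=subset, indel_positions=indel_pos, with_dup=with_dup, **kwargs)
    return sites
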