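"""Identity-by-descent detection and the IBD concordance filter.

A trusted "anchor" marker map is used to find, in windows of 2000 anchor
sites, pairs of taxa whose windowed identity-by-state distance is at most
0.02 (with at least 200 sites comparable) — such pairs are declared
identical by descent in that window and must carry identical genotypes at
any real variant inside it.  Candidate sites are then checked against the
IBD pairs of their window: per allele, concordant pairs count as matches
and discordant ones as mismatches, and the site passes when at least two
alleles reach a match/mismatch ratio of 2, or weakly (flag IBD1) when the
IBD contrasts expose at most one allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gmatrix import ibs_mismatch, is_missing

DEFAULT_WINDOW_SITES = 2000
DEFAULT_IBD_THRESHOLD = 0.02
DEFAULT_MIN_COMPARABLE = 200
DEFAULT_RATIO = 2.0

#: sentinel returned by :func:`ibs_distance` when too few sites are comparable
UNDEFINED = None


@dataclass
class AnchorMap:
    """Trusted-marker genotype matrix used for IBD windows, LD and KNN.

    SNP-only markers; genotypes are unordered pairs of site-allele
    indices (0 = ref, 1 = alt), ``(-1, -1)`` missing.
    """

    chroms: np.ndarray  # (n_sites,) object/str
    positions: np.ndarray  # (n_sites,) int64, sorted within chromosome
    taxa: list[str]
    genotypes: np.ndarray  # (n_sites, n_taxa, 2) int8
    ref: np.ndarray | None = None  # (n_sites,) allele symbols
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape[:2] != (len(self.positions), len(self.taxa)):
            raise ValueError("genotype matrix shape does not match sites x taxa")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.chroms == chrom)[0]

    @classmethod
    def from_vcf(cls, path, taxa: list[str] | None = None) -> "AnchorMap":
        """Load an anchor map from a VCF file (SNP records only)."""
        from .vcfio import read_vcf

        sites, file_taxa = read_vcf(path)
        if taxa is None:
            taxa = file_taxa
        chroms, positions, gts, refs, alts = [], [], [], [], []
        for s in sites:
            if s.is_indel() or len(s.alt_alleles) != 1:
                continue
            chroms.append(s.chrom)
            positions.append(s.pos)
            gts.append(s.genotypes)
            refs.append(s.ref_allele)
            alts.append(s.alt_alleles[0])
        return cls(
            chroms=np.asarray(chroms, dtype=object),
            positions=np.asarray(positions, dtype=np.int64),
            taxa=list(taxa),
            genotypes=np.stack(gts) if gts else np.empty((0, len(taxa), 2), dtype=np.int8),
            ref=np.asarray(refs, dtype=object),
            alt=np.asarray(alts, dtype=object),
        )


@dataclass
class IBDPairSet:
    """IBD taxon pairs per genomic window.

    ``windows`` maps a window id to ``(chrom, start_pos, end_pos,
    first_site_idx, last_site_idx)`` over the anchor; ``pairs_per_window``
    maps the same id to a set of unordered taxon-index pairs, and
    ``distances`` records the windowed IBS distance of each pair.
    """

    taxa: list[str]
    windows: list[tuple] = field(default_factory=list)
    pairs_per_window: list[set] = field(default_factory=list)
    distances: list[dict] = field(default_factory=list)

    def window_for(self, chrom: str, pos: int) -> int | None:
        """Window id containing *pos* on *chrom*; positions beyond the
        anchor span clamp to the chromosome's first/last window."""
        ids = [w for w, win in enumerate(self.windows) if win[0] == chrom]
        if not ids:
            return None
        for w in ids:
            _, start, end, _, _ = self.windows[w]
            if start <= pos <= end:
                return w
        return ids[0] if pos < self.windows[ids[0]][1] else ids[-1]

    def to_dataframe(self):
        """Long-format table: window, chrom, start, end, taxonA, taxonB, distance."""
        import pandas as pd

        rows = []
        for w, (chrom, start, end, _, _) in enumerate(self.windows):
            for (i, j) in sorted(self.pairs_per_window[w]):
                rows.append(
                    {
                        "window": w,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "taxonA": self.taxa[i],
                        "taxonB": self.taxa[j],
                        "distance": self.distances[w][(i, j)],
                    }
                )
        return pd.DataFrame(rows, columns=["window", "chrom", "start", "end", "taxonA", "taxonB", "distance"])


def ibs_distance(gi: np.ndarray, gj: np.ndarray, min_comparable: int = DEFAULT_MIN_COMPARABLE):
    """Windowed IBS distance between two genotype vectors.

    ``d = mean(1 - shared_alleles/2)`` over comparable (both nonmissing)
    sites; het-vs-hom counts 0.5.  Returns ``None`` (UNDEFINED) when
    fewer than *min_comparable* sites are comparable.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have identical shape")
    mm = ibs_mismatch(gi, gj)
    comparable = np.isfinite(mm)
    if comparable.sum() < min_comparable:
        return UNDEFINED
    return float(mm[comparable].mean())


def _chrom_windows(anchor: AnchorMap, window_sites: int):
    """Consecutive non-overlapping windows of *window_sites* anchor sites per
    chromosome; a trailing remainder merges into the previous window."""
    windows = []
    for chrom in dict.fromkeys(anchor.chroms.tolist()):
        idx = anchor.chrom_index(chrom)
        n = len(idx)
        starts = list(range(0, n, window_sites))
        if len(starts) > 1 and n - starts[-1] < window_sites:
            starts = starts[:-1]
        for k, s in enumerate(starts):
            e = starts[k + 1] if k + 1 < len(starts) else n
            windows.append((chrom, idx[s], idx[e - 1]))
    return windows


def find_ibd_pairs(
    anchor: AnchorMap,
    window_sites: int = DEFAULT_WINDOW_SITES,
    threshold: float = DEFAULT_IBD_THRESHOLD,
    min_comparable: int = DEFAULT_MIN_COMPARABLE,
) -> IBDPairSet:
    """Scan anchor windows and collect taxon pairs in IBD.

    A pair enters a window's set iff its windowed IBS distance is defined
    (>= *min_comparable* comparable sites) and <= *threshold*.
    """
    result = IBDPairSet(taxa=list(anchor.taxa))
    nt = anchor.n_taxa
    for chrom, lo, hi in _chrom_windows(anchor, window_sites):
        g = anchor.genotypes[lo : hi + 1]  # (w_sites, n_taxa, 2)
        pairs: set[tuple[int, int]] = set()
        dists: dict[tuple[int, int], float] = {}
        miss = is_missing(g)
        for i in range(nt):
            mm = ibs_mismatch(g[:, i : i + 1, :], g)  # (w_sites, n_taxa)
            comparable = ~(miss[:, i : i + 1] | miss)
            counts = comparable.sum(axis=0)
            with np.errstate(invalid="ignore"):
                d = np.nansum(np.where(comparable, mm, 0.0), axis=0) / np.maximum(counts, 1)
            for j in range(i + 1, nt):
                if counts[j] >= min_comparable and d[j] <= threshold:
                    pairs.add((i, j))
                    dists[(i, j)] = float(d[j])
        result.windows.append(
            (chrom, int(anchor.positions[lo]), int(anchor.positions[hi]), int(lo), int(hi))
        )
        result.pairs_per_window.append(pairs)
        result.distances.append(dists)
    return result


# ---------------------------------------------------------------------------
# the IBD concordance filter
# ---------------------------------------------------------------------------

#: ibd_filter verdicts
CONFIRMED = "confirmed"
IBD1 = "ibd1"
FAIL = "fail"


def ibd_filter(site, pairs: IBDPairSet, min_ratio: float = DEFAULT_RATIO) -> str:
    """Check a tentative site against the IBD pairs of its window.

    Over all IBD pairs with both genotypes nonmissing at the site, each
    site allele *a* accumulates ``match(a) += 1`` for a pair where both
    genotypes carry *a*, and ``mismatch(a) += 1`` where exactly one does
    (a heterozygote carries each of its two alleles).  The site passes as

    * :data:`CONFIRMED` — at least 2 alleles with match/mismatch >=
      *min_ratio* (ratio infinite when mismatch = 0 and match > 0);
    * :data:`IBD1` — confirmation failed but at most one allele appears
      among the IBD-contrast genotypes (the variant is untested rather
      than violated — typical for low-MAF sites);
    * :data:`FAIL` — otherwise.
    """
    w = pairs.window_for(site.chrom, site.pos)
    if w is None:
        return IBD1
    taxon_pairs = pairs.pairs_per_window[w]
    g = site.genotypes
    n_alleles = len(site.alleles)
    match = np.zeros(n_alleles, dtype=np.int64)
    mismatch = np.zeros(n_alleles, dtype=np.int64)
    present: set[int] = set()
    for (i, j) in taxon_pairs:
        gi, gj = g[i], g[j]
        if gi[0] < 0 or gj[0] < 0:
            continue
        ci = set(int(a) for a in gi)
        cj = set(int(a) for a in gj)
        present |= ci | cj
        for a in ci | cj:
            if a in ci and a in cj:
                match[a] += 1
            else:
                mismatch[a] += 1
    ok = 0
    for a in range(n_alleles):
        if mismatch[a] == 0:
            if match[a] > 0:
                ok += 1
        elif match[a] / mismatch[a] >= min_ratio:
            ok += 1
    if ok >= 2:
        return CONFIRMED
    if len(present) <= 1:
        return IBD1
    return FAIL
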