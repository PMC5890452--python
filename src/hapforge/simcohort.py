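"""Synthetic inbred-cohort simulator with full ground truth.

Emulates the population structure the pipeline's filters assume: a panel
of (mostly) inbred taxa descended from a small number of founders.  Each
taxon's genome is a mosaic of founder segments (geometric block lengths),
which plants identity-by-descent blocks between taxa sharing a founder.
Site classes:

* ``true``      — real variants; founders carry the minor allele with a
                  probability drawn from the MAF distribution; a
                  configurable fraction are indels (I/D alleles).
* ``error``     — monomorphic reference sites whose minor-allele reads
                  arise only from sequencing error.
* ``paralog``   — collapsed-paralog sites: a fixed subset of taxa
                  receives a 50/50 mixture of two alleles (systematic
                  heterozygosity from misalignment).
* ``transloc``  — markers whose genotype vector is copied from a distant
                  genomic region (lost collinearity).

Read depths are Poisson with per-taxon mean coverage; each read suffers
a uniform error that moves it to one of the 5 other alleles.  The anchor
map is a subsample of high-MAF true SNP sites at least 5 bp from any
indel, with coverage-driven missingness.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import ALLELE_INDEX, ALLELES, N_ALLELES
from .depthstore import AllelicDepthMatrix
from .ibd import AnchorMap

LABEL_TRUE = "true"
LABEL_ERROR = "error"
LABEL_PARALOG = "paralog"
LABEL_TRANSLOC = "transloc"


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe a small but structurally realistic panel: 50 inbred
    taxa from 5 founders, one 20-Mb chromosome, ×4 mean coverage with
    0.5% per-base error, 1% residual heterozygosity, and MAF drawn
    uniformly from [0.05, 0.5].
    """

    n_taxa: int = 50
    n_founders: int = 5
    chrom_lengths: dict = field(default_factory=lambda: {"1": 20_000_000})
    n_true_sites: int = 2000
    maf_range: tuple = (0.05, 0.5)
    coverage_mean: float = 4.0
    seq_error_rate: float = 0.005
    het_residual_rate: float = 0.01
    n_paralog_sites: int = 0
    n_translocated_sites: int = 0
    n_error_only_sites: int = 0
    anchor_density: float = 0.5
    indel_fraction: float = 0.05
    founder_block_sites_mean: float = 100.0
    paralog_taxon_fraction: float = 0.5
    anchor_min_maf: float = 0.1
    #: infinite-sites mode: each variant allele arises on exactly one founder
    #: haplotype (realized MAF then reflects that founder's panel share)
    single_origin: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_taxa, self.n_founders, self.n_true_sites,
            self.n_paralog_sites, self.n_translocated_sites, self.n_error_only_sites,
        )
        if any(c < 0 for c in counts):
            raise ValueError("site/taxon counts must be non-negative")
        for r in (self.seq_error_rate, self.het_residual_rate, self.indel_fraction,
                  self.paralog_taxon_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 < self.anchor_density <= 1.0:
            raise ValueError("anchor_density must be in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    taxa: list[str]
    sites: pd.DataFrame  # chrom, pos, label, ref, alt, maf, source_index
    genotypes: np.ndarray  # (n_sites, n_taxa, 2) site-allele pairs; what a
    # perfect caller would output (paralog/error sites are ref-hom truth)
    founders: np.ndarray  # (n_sites, n_taxa) founder id per site per taxon

    def label_mask(self, label: str) -> np.ndarray:
        return (self.sites["label"] == label).to_numpy()

    def ibd_pairs_in_window(self, site_indices: np.ndarray) -> set:
        """Taxon pairs sharing the same founder at *every* given site."""
        f = self.founders[site_indices]
        pairs = set()
        n = f.shape[1]
        for i in range(n):
            same = (f == f[:, i : i + 1]).all(axis=0)
            for j in range(i + 1, n):
                if same[j]:
                    pairs.add((i, j))
        return pairs


def _draw_positions(rng, length: int, n: int) -> np.ndarray:
    pos = rng.choice(np.arange(1, length + 1), size=min(n, length), replace=False)
    return np.sort(pos)


def _founder_mosaic(rng, n_sites: int, n_taxa: int, n_founders: int, block_mean: float) -> np.ndarray:
    """Founder assignment per (site, taxon): geometric block lengths in
    units of sites.  In clone mode (block_mean >= n_sites) each taxon is a
    full copy of one founder and the panel descends from the founders in
    balanced proportions, as in a designed diversity panel."""
    f = np.empty((n_sites, n_taxa), dtype=np.int32)
    if block_mean >= n_sites:
        assignment = rng.permutation(np.arange(n_taxa) % n_founders)
        f[:] = assignment[None, :]
        return f
    p = min(1.0, 1.0 / max(block_mean, 1.0))
    for t in range(n_taxa):
        s = 0
        while s < n_sites:
            block = int(rng.geometric(p)) if block_mean > 1 else 1
            f[s : s + block, t] = rng.integers(n_founders)
            s += block
    return f


def simulate_cohort(cfg: SimConfig):
    """Generate a cohort: depth matrices, anchor map, and ground truth.

    Returns
    -------
    (depths, anchor, truth)
        *depths* is a dict chrom -> :class:`AllelicDepthMatrix`;
        *anchor* an :class:`AnchorMap` of trusted true SNPs;
        *truth* a :class:`SimTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"tx{i:03d}" for i in range(cfg.n_taxa)]

    n_extra = cfg.n_error_only_sites + cfg.n_paralog_sites + cfg.n_translocated_sites
    n_total = cfg.n_true_sites + n_extra
    # apportion sites to chromosomes by length
    lengths = cfg.chrom_lengths
    total_len = sum(lengths.values())
    chrom_names = list(lengths)
    site_chrom: list[str] = []
    site_pos: list[int] = []
    counts = {c: int(round(n_total * lengths[c] / total_len)) for c in chrom_names}
    # fix rounding drift on the first chromosome
    counts[chrom_names[0]] += n_total - sum(counts.values())
    for c in chrom_names:
        pos = _draw_positions(rng, lengths[c], counts[c])
        site_chrom += [c] * len(pos)
        site_pos += pos.tolist()
    chroms = np.asarray(site_chrom, dtype=object)
    positions = np.asarray(site_pos, dtype=np.int64)
    n_sites = len(positions)

    # site labels
    labels = np.full(n_sites, LABEL_TRUE, dtype=object)
    extra_idx = rng.choice(n_sites, size=min(n_extra, n_sites), replace=False)
    k = 0
    for lab, cnt in (
        (LABEL_ERROR, cfg.n_error_only_sites),
        (LABEL_PARALOG, cfg.n_paralog_sites),
        (LABEL_TRANSLOC, cfg.n_translocated_sites),
    ):
        labels[extra_idx[k : k + cnt]] = lab
        k += cnt

    # alleles
    ref = rng.integers(0, 4, size=n_sites)
    alt = np.empty(n_sites, dtype=np.int64)
    for s in range(n_sites):
        choices = [a for a in range(4) if a != ref[s]]
        alt[s] = rng.choice(choices)
    is_true = labels == LABEL_TRUE
    indel = np.zeros(n_sites, dtype=bool)
    if cfg.indel_fraction > 0:
        indel = is_true & (rng.random(n_sites) < cfg.indel_fraction)
        alt[indel] = np.where(rng.random(indel.sum()) < 0.5, ALLELE_INDEX["I"], ALLELE_INDEX["D"])

    # founder haplotypes and taxon mosaics
    founders = _founder_mosaic(rng, n_sites, cfg.n_taxa, cfg.n_founders, cfg.founder_block_sites_mean)
    maf = rng.uniform(*cfg.maf_range, size=n_sites)
    if cfg.single_origin:
        founder_carries = np.zeros((n_sites, cfg.n_founders), dtype=bool)
        founder_carries[np.arange(n_sites), rng.integers(cfg.n_founders, size=n_sites)] = True
    else:
        founder_carries = rng.random((n_sites, cfg.n_founders)) < maf[:, None]

    # true genotypes in site-allele space (0 = ref, 1 = alt)
    carries = np.take_along_axis(founder_carries, founders, axis=1)  # (n_sites, n_taxa)
    gt = np.where(carries[..., None], 1, 0).astype(np.int8).repeat(2, axis=-1).reshape(n_sites, cfg.n_taxa, 2)
    # residual heterozygosity
    het_mask = rng.random((n_sites, cfg.n_taxa)) < cfg.het_residual_rate
    gt[het_mask] = (0, 1)
    # monomorphic classes: truth is reference homozygous
    mono = ~is_true
    gt[mono] = 0
    # translocated markers copy the genotype vector of a distant true site
    transloc_idx = np.nonzero(labels == LABEL_TRANSLOC)[0]
    true_idx = np.nonzero(is_true)[0]
    source = np.full(n_sites, -1, dtype=np.int64)
    for s in transloc_idx:
        # the source must be genuinely unlinked: another chromosome when one
        # exists, otherwise far beyond the founder-block scale
        far = true_idx[chroms[true_idx] != chroms[s]]
        if len(far) == 0:
            far = true_idx[np.abs(positions[true_idx] - positions[s]) > 2_000_000]
        if len(far) == 0:
            continue
        src = int(rng.choice(far))
        source[s] = src
        gt[s] = gt[src]

    # paralog sites: a subset of taxa gets a systematic 50/50 allele mixture
    paralog_taxa = {}
    for s in np.nonzero(labels == LABEL_PARALOG)[0]:
        sel = rng.random(cfg.n_taxa) < cfg.paralog_taxon_fraction
        paralog_taxa[int(s)] = sel

    # read depths over the 6-allele space
    depth = np.zeros((n_sites, cfg.n_taxa, N_ALLELES), dtype=np.int64)
    total = rng.poisson(cfg.coverage_mean, size=(n_sites, cfg.n_taxa))
    err = cfg.seq_error_rate
    for s in range(n_sites):
        a_ref, a_alt = int(ref[s]), int(alt[s])
        mixed = paralog_taxa.get(s)
        for t in range(cfg.n_taxa):
            n_reads = int(total[s, t])
            if n_reads == 0:
                continue
            if mixed is not None and mixed[t]:
                src_alleles = (a_ref, a_alt)
                n_a = rng.binomial(n_reads, 0.5)
            elif gt[s, t, 0] != gt[s, t, 1]:
                src_alleles = (a_ref, a_alt)
                n_a = rng.binomial(n_reads, 0.5)
            else:
                src_alleles = (a_ref if gt[s, t, 0] == 0 else a_alt,) * 2
                n_a = n_reads
            for allele, cnt in ((src_alleles[0], n_a), (src_alleles[1], n_reads - n_a)):
                if cnt == 0:
                    continue
                n_err = rng.binomial(cnt, err) if err > 0 else 0
                depth[s, t, allele] += cnt - n_err
                if n_err:
                    others = [a for a in range(N_ALLELES) if a != allele]
                    hits = rng.choice(others, size=n_err)
                    np.add.at(depth[s, t], hits, 1)
    quals = np.where(depth > 0, 35, 0).astype(np.int64)

    truth_sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "label": labels,
            "ref": [ALLELES[a] for a in ref],
            "alt": [ALLELES[a] for a in alt],
            "maf": maf,
            "source_index": source,
        }
    )
    truth = SimTruth(taxa=taxa, sites=truth_sites, genotypes=gt, founders=founders)

    # per-chromosome depth matrices
    depths = {}
    for c in chrom_names:
        sel = chroms == c
        depths[c] = AllelicDepthMatrix(
            c, positions[sel], taxa, depth[sel], quals[sel]
        )

    # anchor: high-MAF true SNPs >= 5 bp from any indel site
    indel_pos_by_chrom = {
        c: positions[(chroms == c) & indel] for c in chrom_names
    }
    eligible = is_true & ~indel & (maf >= cfg.anchor_min_maf)
    elig_idx = np.nonzero(eligible)[0]
    keep = []
    for s in elig_idx:
        ip = indel_pos_by_chrom[str(chroms[s])]
        if len(ip) and np.min(np.abs(ip - positions[s])) <= 5:
            continue
        keep.append(s)
    keep = np.asarray(keep, dtype=np.int64)
    n_anchor = int(round(cfg.anchor_density * len(keep)))
    if n_anchor == 0 and len(keep):
        n_anchor = len(keep)
    anchor_idx = np.sort(rng.choice(keep, size=min(n_anchor, len(keep)), replace=False))

    anchor_gt = gt[anchor_idx].copy()
    # coverage-driven missingness: a genotype is missing when no reads cover it
    p_miss = float(np.exp(-cfg.coverage_mean))
    miss = rng.random(anchor_gt.shape[:2]) < p_miss
    anchor_gt[miss] = (-1, -1)
    anchor = AnchorMap(
        chroms=chroms[anchor_idx],
        positions=positions[anchor_idx],
        taxa=taxa,
        genotypes=anchor_gt,
        ref=np.asarray([ALLELES[a] for a in ref[anchor_idx]], dtype=object),
        alt=np.asarray([ALLELES[a] for a in alt[anchor_idx]], dtype=object),
    )
    return depths, anchor, truth
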