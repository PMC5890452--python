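"""Pipeline orchestration: the strict (LD-filtered) and permissive
(depth-filtered + imputed) routes.

Both routes share discovery → segregation-test filter → IBD filter.  The
strict route then applies the LD filter against the anchor map and emits
sites flagged LLD/IBD1/NI5/FH/FH2; the permissive route applies the
">1, >2" minor-depth filter, imputes missing genotypes with LD-KNN, and
emits DUP/MAF0/Imp* annotations plus INHMP311 marking membership in the
strict set.  A run report records per-stage attrition
(sites_in = sites_out + sites_rejected) and reruns with the same seed
are byte-identical (per-site RNG streams keyed by coordinates).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import imputeknn
from .depthstore import AllelicDepthMatrix
from .genotyper import TentativeSite, discover_site, minor_depth_filter
from .ibd import FAIL, IBD1, AnchorMap, find_ibd_pairs, ibd_filter
from .ldfilter import PASS_LLD, REJECT, ld_filter
from .segtest import st_filter
from .vcfio import write_vcf

ROUTE_STRICT = "strict"
ROUTE_PERMISSIVE = "permissive"
ROUTE_BOTH = "both"


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's canonical values."""

    route: str = ROUTE_BOTH
    seed: int = 0
    # discovery
    baseq_min: int = 10
    mapq_min: int = 30
    min_covered_taxa: int = 10
    error_rate: float = 0.01
    # segregation test
    st_alpha: float = 0.01
    st_chisq_gate: float = 0.2
    st_replicates: int = 2000
    # IBD
    ibd_window_sites: int = 2000
    ibd_threshold: float = 0.02
    ibd_min_comparable: int = 200
    ibd_min_ratio: float = 2.0
    # LD filter
    ld_min_bp: int = 2500
    ld_min_taxa: int = 40
    ld_min_minor: int = 2
    ld_max_hits: int = 20
    ld_best_p_max: float = 1e-6
    ld_local_radius_bp: float = 1_000_000
    ld_local_factor: float = 10.0
    # imputation
    imp_window_bp: int = 600_000
    imp_max_ld_sites: int = 70
    imp_het_max: float = 0.03
    imp_presence_min: float = 0.5
    imp_max_d: float = 0.1
    imp_min_common: int = 10
    imp_max_missing: float = 0.5
    imp_k: int = 30
    imp_weight_scale: float = 70.0
    imp_dominance: float = 10.0
    imp_maf_fallback: float = 0.01
    # annotation
    fh_chrom: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class StageCount:
    sites_in: int
    sites_out: int

    @property
    def sites_rejected(self) -> int:
        return self.sites_in - self.sites_out


@dataclass
class RunReport:
    """Per-stage site attrition for one pipeline run."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, sites_in: int, sites_out: int) -> None:
        self.stages[stage] = StageCount(sites_in, sites_out)

    def to_dict(self) -> dict:
        return {
            k: {"in": v.sites_in, "out": v.sites_out, "rejected": v.sites_rejected}
            for k, v in self.stages.items()
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def discover_sites(
    depths: dict[str, AllelicDepthMatrix],
    ref_alleles: dict[str, np.ndarray],
    cfg: PipelineConfig,
) -> list[TentativeSite]:
    """Run tentative-site discovery over per-chromosome depth matrices.

    *ref_alleles* maps chromosome -> array of reference allele symbols
    aligned with the matrix positions.
    """
    sites = []
    for chrom in depths:
        m = depths[chrom]
        refs = ref_alleles[chrom]
        if len(refs) != m.n_sites:
            raise ValueError(f"{chrom}: reference allele array does not match positions")
        for s in range(m.n_sites):
            site = discover_site(
                chrom,
                int(m.positions[s]),
                m.depths[s],
                m.quals[s],
                str(refs[s]),
                min_covered_taxa=cfg.min_covered_taxa,
                error_rate=cfg.error_rate,
            )
            if site is not None:
                sites.append(site)
    return sites


def prune_alt_alleles(site: TentativeSite, kept_alts: list[str]) -> TentativeSite | None:
    """Restrict a site to ref + *kept_alts*; genotypes carrying a removed
    allele become missing.  Returns None when no alt allele survives."""
    if not kept_alts:
        return None
    if kept_alts == site.alt_alleles:
        return site
    old_alleles = site.alleles
    keep_idx = [0] + [old_alleles.index(a) for a in kept_alts]
    remap = {old: new for new, old in enumerate(keep_idx)}
    g = site.genotypes
    new_g = np.full_like(g, -1)
    for t in range(g.shape[0]):
        a0, a1 = int(g[t, 0]), int(g[t, 1])
        if a0 >= 0 and a0 in remap and a1 in remap:
            n0, n1 = remap[a0], remap[a1]
            new_g[t] = (min(n0, n1), max(n0, n1))
    return replace(
        site,
        alt_alleles=list(kept_alts),
        genotypes=new_g,
        allele_depths=site.allele_depths[:, keep_idx],
        mean_quals=site.mean_quals[keep_idx],
    )


def apply_st_filter(sites: list[TentativeSite], cfg: PipelineConfig) -> list[TentativeSite]:
    out = []
    for site in sites:
        kept, pv = st_filter(
            site,
            alpha=cfg.st_alpha,
            replicates=cfg.st_replicates,
            seed=cfg.seed,
            chisq_gate=cfg.st_chisq_gate,
        )
        pruned = prune_alt_alleles(site, kept)
        if pruned is not None:
            pruned.info["PV"] = pv
            out.append(pruned)
    return out


def apply_ibd_filter(sites, pairs, cfg: PipelineConfig):
    out = []
    for site in sites:
        verdict = ibd_filter(site, pairs, min_ratio=cfg.ibd_min_ratio)
        if verdict == FAIL:
            continue
        if verdict == IBD1:
            site.flags.add("IBD1")
        out.append(site)
    return out


def apply_ld_filter(sites, anchor: AnchorMap, cfg: PipelineConfig):
    out = []
    for site in sites:
        verdict, _ = ld_filter(
            site,
            anchor,
            max_hits=cfg.ld_max_hits,
            best_p_max=cfg.ld_best_p_max,
            local_radius=cfg.ld_local_radius_bp,
            local_factor=cfg.ld_local_factor,
            min_bp=cfg.ld_min_bp,
            min_taxa=cfg.ld_min_taxa,
            min_minor=cfg.ld_min_minor,
        )
        if verdict == REJECT:
            continue
        if verdict == PASS_LLD:
            site.flags.add("LLD")
        out.append(site)
    return out


def apply_minor_depth_filter(sites, cfg: PipelineConfig):
    out = []
    for site in sites:
        pruned = prune_alt_alleles(site, minor_depth_filter(site))
        if pruned is not None:
            out.append(pruned)
    return out


def apply_imputation(sites: list[TentativeSite], cfg: PipelineConfig):
    """Impute missing genotypes across a site list; annotates MAF0 and the
    Imp* accuracies and returns the imputation result."""
    if not sites:
        return None
    g = np.stack([s.genotypes for s in sites])
    positions = np.asarray([s.pos for s in sites], dtype=np.int64)
    chroms = np.asarray([s.chrom for s in sites], dtype=object)
    indel = np.asarray([s.is_indel() for s in sites], dtype=bool)
    res = imputeknn.impute_matrix(
        g,
        positions,
        chroms,
        indel_sites=indel,
        maf_fallback=cfg.imp_maf_fallback,
        window_bp=cfg.imp_window_bp,
        max_ld_sites=cfg.imp_max_ld_sites,
        het_max=cfg.imp_het_max,
        presence_min=cfg.imp_presence_min,
        max_d=cfg.imp_max_d,
        min_common=cfg.imp_min_common,
        max_missing=cfg.imp_max_missing,
        k=cfg.imp_k,
        weight_scale=cfg.imp_weight_scale,
        dominance=cfg.imp_dominance,
    )
    for i, site in enumerate(sites):
        site.genotypes = res.genotypes[i]
        site.info["MAF0"] = float(res.maf0[i])
        if np.isfinite(res.imp_homo_accuracy[i]):
            site.info["ImpHomoAccuracy"] = float(res.imp_homo_accuracy[i])
        if np.isfinite(res.imp_minor_accuracy[i]):
            site.info["ImpMinorAccuracy"] = float(res.imp_minor_accuracy[i])
    return res


def run_pipeline(
    depths: dict[str, AllelicDepthMatrix],
    ref_alleles: dict[str, np.ndarray],
    anchor: AnchorMap,
    cfg: PipelineConfig,
    out_dir,
    taxa: list[str] | None = None,
) -> RunReport:
    """Run the full pipeline and write annotated VCF(s) plus a report.

    Outputs under *out_dir*: ``strict.vcf`` (LD route) and/or
    ``permissive.vcf`` (depth-filter + imputation route), and
    ``report.json`` with per-stage attrition counts.
    """
    if cfg.route not in (ROUTE_STRICT, ROUTE_PERMISSIVE, ROUTE_BOTH):
        raise ValueError(f"unknown route: {cfg.route}")
    if cfg.route in (ROUTE_STRICT, ROUTE_BOTH) and anchor is None:
        raise ValueError("the LD filter requires an anchor map")
    if anchor is None:
        raise ValueError("the IBD filter requires an anchor map")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if taxa is None:
        taxa = next(iter(depths.values())).taxa
    report = RunReport()

    sites = discover_sites(depths, ref_alleles, cfg)
    n_positions = sum(m.n_sites for m in depths.values())
    report.record("discovery", n_positions, len(sites))

    st_sites = apply_st_filter(sites, cfg)
    report.record("st_filter", len(sites), len(st_sites))

    pairs = find_ibd_pairs(
        anchor,
        window_sites=cfg.ibd_window_sites,
        threshold=cfg.ibd_threshold,
        min_comparable=cfg.ibd_min_comparable,
    )
    ibd_sites = apply_ibd_filter(st_sites, pairs, cfg)
    report.record("ibd_filter", len(st_sites), len(ibd_sites))

    strict_keys: set[tuple[str, int]] = set()
    if cfg.route in (ROUTE_STRICT, ROUTE_BOTH):
        import copy

        strict_sites = apply_ld_filter([copy.deepcopy(s) for s in ibd_sites], anchor, cfg)
        report.record("ld_filter", len(ibd_sites), len(strict_sites))
        # DUP is a permissive-route flag; the strict route emits FH/FH2 instead
        ann.annotate_sites(strict_sites, designated_chrom=cfg.fh_chrom, with_fh=True, with_dup=False)
        strict_keys = {(s.chrom, s.pos) for s in strict_sites}
        write_vcf(strict_sites, taxa, out_dir / "strict.vcf")

    if cfg.route in (ROUTE_PERMISSIVE, ROUTE_BOTH):
        import copy

        perm_sites = apply_minor_depth_filter([copy.deepcopy(s) for s in ibd_sites], cfg)
        report.record("minor_depth_filter", len(ibd_sites), len(perm_sites))
        # DUP is decided on the unimputed genotypes
        ann.annotate_sites(perm_sites, with_fh=False, with_ni5=False, with_dup=True)
        apply_imputation(perm_sites, cfg)
        # numeric annotations describe the genotypes actually written
        ann.annotate_sites(perm_sites, with_fh=False, with_ni5=True, with_dup=False)
        if cfg.route == ROUTE_BOTH:
            for s in perm_sites:
                if (s.chrom, s.pos) in strict_keys:
                    s.flags.add("INHMP311")
        write_vcf(perm_sites, taxa, out_dir / "permissive.vcf")

    report.save(out_dir / "report.json")
    return report
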