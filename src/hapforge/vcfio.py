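"""Reading and writing annotated VCF 4.2 files.

Sites are written with per-taxon ``GT:AD`` fields and the INFO keys of
the pipeline's annotation set.  The indel pseudo-alleles I and D are
represented as the symbolic ALT alleles ``<INS>`` and ``<DEL>``.
Reading goes through cyvcf2 and reconstructs
:class:`~hapforge.genotyper.TentativeSite` records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genotyper import TentativeSite

#: INFO field definitions: key -> (Number, Type, Description)
INFO_FIELDS = {
    "DP": ("1", "Integer", "Total read depth at the site"),
    "NZ": ("1", "Integer", "Number of taxa with called genotypes"),
    "AD": (".", "Integer", "Allelic depths (reference, alternative in ALT order)"),
    "AC": (".", "Integer", "Numbers of alternative alleles in ALT order"),
    "AQ": (".", "Integer", "Average allele base qualities (reference, alternative in ALT order)"),
    "GN": (".", "Integer", "Numbers of genotypes (AA,AB,BB or AA,AB,AC,BB,BC,CC if 2 alt alleles)"),
    "HT": ("1", "Integer", "Number of heterozygotes"),
    "EF": ("1", "Float", "het_frequency/(presence_frequency*minor_allele_frequency)"),
    "PV": ("1", "Float", "P-value from segregation test"),
    "MAF": ("1", "Float", "Minor allele frequency (summed over all alternative alleles)"),
    "MAF0": ("1", "Float", "Minor allele frequency before imputation"),
    "FH": ("1", "Float", "Fraction of heterozygous taxa among high-coverage taxa"),
    "ImpHomoAccuracy": ("1", "Float", "Fraction of homozygotes imputed back into homozygotes"),
    "ImpMinorAccuracy": ("1", "Float", "Fraction of minor allele homozygotes imputed back into minor allele homozygotes"),
}

FLAG_FIELDS = {
    "FH2": "Site with FH greater than 2%",
    "IBD1": "Only 1 allele present in IBD contrasts",
    "LLD": "Site in local LD with the anchor map",
    "NI5": "Indel or site within 5 bp of a putative indel",
    "INHMP311": "Site present in the strictly filtered (LD-route) set",
    "DUP": "Site with heterozygote frequency >3%",
}

_SYMBOLIC = {"I": "<INS>", "D": "<DEL>"}
_SYMBOLIC_BACK = {"<INS>": "I", "<DEL>": "D"}


def _allele_to_vcf(symbol: str) -> str:
    return _SYMBOLIC.get(symbol, symbol)


def _allele_from_vcf(allele: str) -> str:
    return _SYMBOLIC_BACK.get(allele, allele)


def _format_info_value(v) -> str:
    if isinstance(v, float) or isinstance(v, np.floating):
        if np.isnan(v):
            return "."
        return f"{v:.6g}"
    if isinstance(v, (list, tuple, np.ndarray)):
        return ",".join(_format_info_value(x) for x in v)
    return str(v)


class VCFValidationError(ValueError):
    """Raised when a record is inconsistent with its genotypes."""


def write_vcf(sites: list[TentativeSite], taxa: list[str], path) -> Path:
    """Write sites with GT:AD per taxon and their INFO annotations.

    Sites must carry genotypes over their own allele list; INFO values
    come from ``site.info`` and flags from ``site.flags``.
    """
    path = Path(path)
    chroms = list(dict.fromkeys(s.chrom for s in sites))
    lines = ["##fileformat=VCFv4.2", "##source=hapforge"]
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    for key, (num, typ, desc) in INFO_FIELDS.items():
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    for key, desc in FLAG_FIELDS.items():
        lines.append(f'##INFO=<ID={key},Number=0,Type=Flag,Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=.,Type=Integer,Description="Allelic depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(taxa))

    for s in sites:
        if s.genotypes.shape[0] != len(taxa):
            raise VCFValidationError(f"{s.chrom}:{s.pos}: genotype count != taxa count")
        n_alleles = len(s.alleles)
        if s.genotypes.max(initial=-1) >= n_alleles:
            raise VCFValidationError(f"{s.chrom}:{s.pos}: genotype allele index out of range")
        alt = ",".join(_allele_to_vcf(a) for a in s.alt_alleles) or "."
        info_parts = []
        for key in INFO_FIELDS:
            if key in s.info and s.info[key] is not None:
                val = _format_info_value(s.info[key])
                if val != ".":  # undefined values are omitted, not written as '.'
                    info_parts.append(f"{key}={val}")
        for key in FLAG_FIELDS:
            if key in s.flags:
                info_parts.append(key)
        info = ";".join(info_parts) or "."
        cols = [s.chrom, str(s.pos), ".", s.ref_allele, alt, ".", "PASS", info, "GT:AD"]
        for t in range(len(taxa)):
            a0, a1 = int(s.genotypes[t, 0]), int(s.genotypes[t, 1])
            gt = "./." if a0 < 0 else f"{a0}/{a1}"
            ad = ",".join(str(int(x)) for x in s.allele_depths[t])
            cols.append(f"{gt}:{ad}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path) -> tuple[list[TentativeSite], list[str]]:
    """Read a VCF written by :func:`write_vcf` (or compatible) back into
    site records.  Returns (sites, taxa)."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    taxa = list(vcf.samples)
    sites: list[TentativeSite] = []
    for var in vcf:
        alts = [_allele_from_vcf(a) for a in var.ALT]
        n_alleles = 1 + len(alts)
        n_taxa = len(taxa)
        gts = np.full((n_taxa, 2), -1, dtype=np.int8)
        for t, g in enumerate(var.genotypes):
            a0, a1 = g[0], g[1]
            if a0 >= 0 and a1 >= 0:
                gts[t, 0], gts[t, 1] = min(a0, a1), max(a0, a1)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            ad = np.zeros((n_taxa, n_alleles), dtype=np.int64)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0
            if ad.shape[1] != n_alleles:
                ad = ad[:, :n_alleles]
        info = {}
        flags = set()
        for key in INFO_FIELDS:
            v = var.INFO.get(key)
            if v is not None:
                info[key] = v
        for key in FLAG_FIELDS:
            if var.INFO.get(key) is not None:
                flags.add(key)
        aq = info.get("AQ")
        mean_quals = (
            np.atleast_1d(np.asarray(aq, dtype=np.int64))
            if aq is not None
            else np.zeros(n_alleles, dtype=np.int64)
        )
        sites.append(
            TentativeSite(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_alleles=alts,
                genotypes=gts,
                allele_depths=ad,
                mean_quals=mean_quals,
                info=info,
                flags=flags,
            )
        )
    vcf.close()
    return sites, taxa
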