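"""The fixed six-allele space used throughout the pipeline.

SNP genotyping over a single reference treats insertions and deletions as
two extra pseudo-alleles ``I`` and ``D``, regardless of indel length or
sequence, giving the ordered allele space ``A, C, G, T, I, D``.  The order
is fixed and identical everywhere: depth cubes, likelihood tables and VCF
allele lists all index into it.
"""

from __future__ import annotations

#: Ordered allele symbols; indices into this tuple are used pipeline-wide.
ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "I", "D")

#: Number of alleles in the space.
N_ALLELES: int = len(ALLELES)

#: Symbol -> index lookup.
ALLELE_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}

#: Indices of the indel pseudo-alleles.
INDEL_INDICES: frozenset[int] = frozenset({ALLELE_INDEX["I"], ALLELE_INDEX["D"]})


def allele_index(symbol: str) -> int:
    """Return the index of *symbol* in the 6-allele space.

    Raises
    ------
    ValueError
        If the symbol is not one of A, C, G, T, I, D.
    """
    try:
        return ALLELE_INDEX[symbol.upper()]
    except KeyError:
        raise ValueError(f"unknown allele symbol: {symbol!r}") from None


def is_indel_symbol(symbol: str) -> bool:
    """True if *symbol* is one of the indel pseudo-alleles I/D."""
    return symbol.upper() in ("I", "D")
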