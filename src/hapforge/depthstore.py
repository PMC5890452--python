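"""Per-taxon allelic depth storage: one-byte codec, HDF5 stores, pileup parsing.

Allelic depths and mean base qualities are kept per (site, taxon, allele)
over the 6-allele space.  To keep per-taxon per-chromosome stores small,
each count is packed into a single signed byte: integers 0..182 are stored
exactly as non-negative codes, while larger counts (up to 10 000) are
mapped onto a geometric grid addressed by the 73 negative codes, giving a
maximum relative round-trip error below 3.1%.  Counts above 10 000
saturate at the largest representable value.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .alleles import ALLELE_INDEX, ALLELES, N_ALLELES

# ---------------------------------------------------------------------------
# one-byte depth/quality codec
# ---------------------------------------------------------------------------

#: Largest integer represented exactly.
EXACT_MAX = 182
#: Number of negative codes available in a signed byte below -0.
N_NEG_CODES = 73
#: Largest representable count; everything above saturates.
MAX_DEPTH = 10_000

# geometric grid: code -k (k = 1..73) represents round(183 * BASE**k),
# chosen so that the grid spans (182, 10000] with uniform relative steps.
_BASE = (MAX_DEPTH / (EXACT_MAX + 1)) ** (1.0 / N_NEG_CODES)

#: decode table indexed by code (0..182 exact, then codes -1..-73 appended).
_DECODE = np.concatenate(
    [
        np.arange(EXACT_MAX + 1, dtype=np.int64),
        np.rint((EXACT_MAX + 1) * _BASE ** np.arange(1, N_NEG_CODES + 1)).astype(np.int64),
    ]
)
# midpoints between consecutive representable values; encode() picks the
# nearest representable value, which is what bounds the relative error.
_MIDPOINTS = (_DECODE[:-1] + _DECODE[1:]) / 2.0


def encode_count(x):
    """Encode non-negative counts into signed one-byte codes.

    Codes 0..182 are the identity; codes -1..-73 address a geometric grid
    covering 183..10000; larger values saturate at code -73.  Encoding is
    monotone non-decreasing and maps each value to the nearest
    representable grid point.

    Parameters
    ----------
    x : int or array-like of int
        Count(s) >= 0.

    Returns
    -------
    int or ndarray of int16
        Code in {0..182} ∪ {-1..-73}; :func:`_code_to_slot` packs codes
        into single bytes for storage.
    """
    arr = np.asarray(x)
    if np.any(arr < 0):
        raise ValueError("depth/quality counts must be non-negative")
    slot = np.searchsorted(_MIDPOINTS, np.minimum(arr, MAX_DEPTH))
    code = np.where(slot <= EXACT_MAX, slot, EXACT_MAX - slot).astype(np.int16)
    if np.isscalar(x) or arr.ndim == 0:
        return int(code)
    return code


def _code_to_slot(code: np.ndarray) -> np.ndarray:
    """Map codes (0..182, -1..-73) onto the 256 one-byte slots 0..255."""
    code = np.asarray(code, dtype=np.int64)
    return np.where(code >= 0, code, EXACT_MAX - code).astype(np.uint8)


def _slot_to_code(slot: np.ndarray) -> np.ndarray:
    slot = np.asarray(slot, dtype=np.int64)
    return np.where(slot <= EXACT_MAX, slot, EXACT_MAX - slot).astype(np.int16)


def decode_count(code):
    """Decode one-byte codes back to counts (total on the byte range).

    Inverse of :func:`encode_count` on 0..182; negative codes return the
    grid value they address.  Codes below -73 clamp to the largest grid
    value, codes above 182 are not produced by the encoder but decode as
    the exact value capped at 182.
    """
    arr = np.asarray(code, dtype=np.int64)
    slot = np.where(arr >= 0, np.minimum(arr, EXACT_MAX), EXACT_MAX + np.minimum(-arr, N_NEG_CODES))
    out = _DECODE[slot]
    if np.isscalar(code) or arr.ndim == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# in-memory container
# ---------------------------------------------------------------------------


@dataclass
class AllelicDepthMatrix:
    """Per-site × per-taxon × per-allele read depths and mean base qualities.

    Attributes
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int64
        1-based coordinates, strictly increasing.
    taxa : list of str
        Ordered taxon names.
    depths : ndarray, shape (n_sites, n_taxa, 6)
        Read depth per allele.
    quals : ndarray, shape (n_sites, n_taxa, 6)
        Mean phred base quality per allele (0 where depth is 0).
    """

    chrom: str
    positions: np.ndarray
    taxa: list[str]
    depths: np.ndarray
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.quals = np.asarray(self.quals, dtype=np.int64)
        n = len(self.positions)
        if self.depths.shape != (n, len(self.taxa), N_ALLELES):
            raise ValueError(
                f"depth cube shape {self.depths.shape} does not match "
                f"{n} sites x {len(self.taxa)} taxa x {N_ALLELES} alleles"
            )
        if self.quals.shape != self.depths.shape:
            raise ValueError("qual cube shape must match depth cube shape")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def total_depth(self) -> np.ndarray:
        """Total depth per (site, taxon), summed over alleles."""
        return self.depths.sum(axis=2)


# ---------------------------------------------------------------------------
# HDF5 stores: one file per taxon, one group per chromosome
# ---------------------------------------------------------------------------


def save_store(matrix: AllelicDepthMatrix, directory) -> list[Path]:
    """Persist a depth matrix as per-taxon HDF5 stores.

    One file per taxon is written under *directory* (``<taxon>.h5``), with
    one group per chromosome containing datasets ``positions``,
    ``depth_codes`` (sites × 6, int8) and ``qual_codes`` (sites × 6, int8).
    Only sites with non-zero total coverage in a taxon are stored for that
    taxon.  Existing stores for the same taxa gain/replace the chromosome
    group.

    Returns the list of file paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    total = matrix.total_depth()
    for j, taxon in enumerate(matrix.taxa):
        covered = total[:, j] > 0
        path = directory / f"{taxon}.h5"
        with h5py.File(path, "a") as f:
            if matrix.chrom in f:
                del f[matrix.chrom]
            grp = f.create_group(matrix.chrom)
            grp.create_dataset("positions", data=matrix.positions[covered])
            grp.create_dataset(
                "depth_codes",
                data=_code_to_slot(encode_count(matrix.depths[covered, j, :])),
                dtype="u1",
            )
            grp.create_dataset(
                "qual_codes",
                data=_code_to_slot(encode_count(matrix.quals[covered, j, :])),
                dtype="u1",
            )
        written.append(path)
    return written


def load_store(directory, chrom: str, taxa: list[str] | None = None) -> AllelicDepthMatrix:
    """Load per-taxon HDF5 stores back into a dense :class:`AllelicDepthMatrix`.

    Parameters
    ----------
    directory : path
        Directory holding ``<taxon>.h5`` stores.
    chrom : str
        Chromosome group to load.
    taxa : list of str, optional
        Taxon order; defaults to the sorted ``*.h5`` file stems.

    Raises
    ------
    FileNotFoundError
        If the directory or a requested taxon store is missing.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"depth store directory not found: {directory}")
    if taxa is None:
        taxa = sorted(p.stem for p in directory.glob("*.h5"))
        if not taxa:
            raise FileNotFoundError(f"no depth stores (*.h5) in {directory}")

    per_taxon = []
    all_positions = set()
    for taxon in taxa:
        path = directory / f"{taxon}.h5"
        if not path.exists():
            raise FileNotFoundError(f"missing depth store: {path}")
        with h5py.File(path, "r") as f:
            if chrom in f:
                grp = f[chrom]
                pos = grp["positions"][()]
                dep = decode_count(_slot_to_code(grp["depth_codes"][()]))
                qua = decode_count(_slot_to_code(grp["qual_codes"][()]))
            else:
                pos = np.empty(0, dtype=np.int64)
                dep = np.empty((0, N_ALLELES), dtype=np.int64)
                qua = np.empty((0, N_ALLELES), dtype=np.int64)
        per_taxon.append((pos, dep, qua))
        all_positions.update(pos.tolist())

    positions = np.array(sorted(all_positions), dtype=np.int64)
    n = len(positions)
    depths = np.zeros((n, len(taxa), N_ALLELES), dtype=np.int64)
    quals = np.zeros((n, len(taxa), N_ALLELES), dtype=np.int64)
    for j, (pos, dep, qua) in enumerate(per_taxon):
        if len(pos):
            idx = np.searchsorted(positions, pos)
            depths[idx, j, :] = dep
            quals[idx, j, :] = qua
    return AllelicDepthMatrix(chrom, positions, list(taxa), depths, quals)


# ---------------------------------------------------------------------------
# pileup parsing
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


class PileupParseError(ValueError):
    """Raised when a pileup line cannot be interpreted."""


@dataclass
class _SiteAccumulator:
    depth: np.ndarray = field(default_factory=lambda: np.zeros(N_ALLELES, dtype=np.int64))
    qual_sum: np.ndarray = field(default_factory=lambda: np.zeros(N_ALLELES, dtype=np.int64))

    def add(self, allele: int, qual: int, baseq_min: int) -> None:
        if qual < baseq_min:
            return
        self.depth[allele] += 1
        self.qual_sum[allele] += qual


def _parse_bases(bases: str, quals: str, ref_idx: int, baseq_min: int, lineno: int) -> _SiteAccumulator:
    acc = _SiteAccumulator()
    i = 0  # index into bases
    q = 0  # index into quals
    last_qual = 0  # quality of the base directly preceding an indel
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # read start: skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise PileupParseError(f"line {lineno}: malformed indel at column {i}")
            length = int(m.group(1))
            allele = ALLELE_INDEX["I"] if c == "+" else ALLELE_INDEX["D"]
            # indel quality = quality of the base directly preceding it
            acc.add(allele, last_qual, baseq_min)
            i = m.end() + length
            continue
        # every remaining supported symbol consumes one quality character
        if q >= len(quals):
            raise PileupParseError(f"line {lineno}: base/quality string length mismatch")
        qual = ord(quals[q]) - 33
        q += 1
        if c in ".,":
            acc.add(ref_idx, qual, baseq_min)
        elif c.upper() in "ACGT":
            acc.add(ALLELE_INDEX[c.upper()], qual, baseq_min)
        elif c == "*":
            # deleted base: counts toward the D allele at this position
            acc.add(ALLELE_INDEX["D"], qual, baseq_min)
        else:
            raise PileupParseError(f"line {lineno}: unsupported pileup symbol {c!r}")
        last_qual = qual
        i += 1
    if q != len(quals):
        raise PileupParseError(f"line {lineno}: base/quality string length mismatch")
    return acc


def depths_from_pileup(source, taxon: str, baseq_min: int = 10, mapq_min: int = 30) -> AllelicDepthMatrix:
    """Parse single-sample pileup text into an :class:`AllelicDepthMatrix`.

    The pileup is assumed to come from ``samtools mpileup`` run on one
    taxon with the mapping-quality threshold (*mapq_min*, default 30)
    already imposed upstream; the base-quality threshold (*baseq_min*,
    default 10) is applied here from the quality string.  Insertions and
    deletions collapse onto the I/D pseudo-alleles; an indel's quality is
    that of the base directly preceding it.

    Parameters
    ----------
    source : path or str or iterable of lines
        Path to a pileup file (optionally gzip-compressed), pileup text,
        or an iterable of lines.
    taxon : str
        Taxon name for the resulting matrix.
    """
    close = None
    if isinstance(source, (str, Path)) and ("\t" not in str(source)) and Path(str(source)).exists():
        p = Path(source)
        fh = gzip.open(p, "rt") if p.suffix == ".gz" else open(p)
        lines = fh
        close = fh
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source

    chrom = None
    positions: list[int] = []
    depth_rows: list[np.ndarray] = []
    qual_rows: list[np.ndarray] = []
    try:
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PileupParseError(f"line {lineno}: expected >=6 tab-separated fields")
            chr_, pos_s, ref, depth_s, bases, quals = fields[:6]
            if chrom is None:
                chrom = chr_
            elif chr_ != chrom:
                raise PileupParseError(f"line {lineno}: multiple chromosomes in one pileup")
            try:
                pos = int(pos_s)
                int(depth_s)
            except ValueError:
                raise PileupParseError(f"line {lineno}: non-integer position/depth") from None
            if ref.upper() not in "ACGT":
                raise PileupParseError(f"line {lineno}: unsupported reference base {ref!r}")
            acc = _parse_bases(bases, quals, ALLELE_INDEX[ref.upper()], baseq_min, lineno)
            if acc.depth.sum() == 0:
                continue
            positions.append(pos)
            depth_rows.append(acc.depth)
            mean_q = np.zeros(N_ALLELES, dtype=np.int64)
            nz = acc.depth > 0
            mean_q[nz] = np.rint(acc.qual_sum[nz] / acc.depth[nz]).astype(np.int64)
            qual_rows.append(mean_q)
    finally:
        if close is not None:
            close.close()

    n = len(positions)
    depths = np.stack(depth_rows)[:, None, :] if n else np.empty((0, 1, N_ALLELES), dtype=np.int64)
    quals = np.stack(qual_rows)[:, None, :] if n else np.empty((0, 1, N_ALLELES), dtype=np.int64)
    return AllelicDepthMatrix(
        chrom or "unknown", np.asarray(positions, dtype=np.int64), [taxon], depths, quals
    )
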