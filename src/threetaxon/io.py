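"""Alignment and tree I/O, supermatrix assembly, taxon subsetting.

Alignments are dense symbol matrices over the nucleotide alphabet plus IUPAC
ambiguity codes, gap '-' and missing '?'.  Gap and missing are distinct at
this level; how parsimony treats them is decided in :mod:`.parsimony`.

Format parsing goes through Biopython (FASTA, relaxed PHYLIP, NEXUS); trees
go through dendropy.  Taxon labels are normalized by mapping internal
whitespace to underscores; comparisons stay case-sensitive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
import dendropy

from .trees import Tree

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTRYSWKMBDHVN-?")

#: nucleotide bitmasks: A=1 C=2 G=4 T=8; ambiguity = union; gap/missing/N = all
STATE_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14,
    "N": 15, "-": 15, "?": 15,
}


class FormatError(ValueError):
    """Raised for malformed alignment or tree input."""


def normalize_label(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


@dataclass
class Alignment:
    """Taxa-by-columns symbol matrix.

    ``data`` is a 2-D array of single-character strings, uppercased, every
    symbol drawn from the declared alphabet.
    """

    taxa: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if len(self.taxa) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon labels: {dupes}")
        bad = ~np.isin(self.data, sorted(ALPHABET))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"invalid symbol {self.data[r, c]!r} at taxon "
                f"{self.taxa[r]!r}, column {c}"
            )

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def masks(self) -> np.ndarray:
        """uint8 state-set bitmask matrix (A=1, C=2, G=4, T=8)."""
        out = np.zeros(self.data.shape, dtype=np.uint8)
        for sym, mask in STATE_MASKS.items():
            out[self.data == sym] = mask
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )


@dataclass
class PartitionMap:
    """Ordered loci as 0-based half-open column intervals."""

    loci: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        pos = 0
        for name, start, end in self.loci:
            if start != pos or end <= start:
                raise FormatError(
                    f"partition {name!r} [{start},{end}) is not contiguous from {pos}"
                )
            pos = end

    @property
    def ncols(self) -> int:
        return self.loci[-1][2] if self.loci else 0

    def names(self) -> list[str]:
        return [n for n, _, _ in self.loci]


# --------------------------------------------------------------- alignments


def _from_biopython(msa) -> Alignment:
    # FASTA headers may contain spaces; the whole header is the label
    taxa = [normalize_label(rec.description or rec.id) for rec in msa]
    rows = [list(str(rec.seq).upper()) for rec in msa]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
    return Alignment(taxa, np.array(rows, dtype="<U1"))


_FORMAT_NAMES = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA / relaxed-PHYLIP / NEXUS alignment.

    Symbols are uppercased; anything outside the alphabet is rejected with
    the offending taxon and column named.
    """
    if format not in _FORMAT_NAMES:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMAT_NAMES)}")
    path = Path(path)
    if format == "nexus":
        text = path.read_text().lower()
        for block in ("begin sets", "begin assumptions"):
            if block in text:
                logger.warning("%s: ignoring %s block", path, block.upper())
    try:
        msa = AlignIO.read(str(path), _FORMAT_NAMES[format])
    except FormatError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_biopython(msa)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    rows = ["".join(r) for r in aln.data]
    if format == "fasta":
        with open(path, "w") as fh:
            for taxon, seq in zip(aln.taxa, rows):
                fh.write(f">{taxon}\n{seq}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.ntaxa} {aln.ncols}\n")
            for taxon, seq in zip(aln.taxa, rows):
                fh.write(f"{taxon}  {seq}\n")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={aln.ntaxa} NCHAR={aln.ncols};\n")
            fh.write('  FORMAT DATATYPE=DNA GAP=- MISSING=?;\n  MATRIX\n')
            for taxon, seq in zip(aln.taxa, rows):
                fh.write(f"    {taxon}  {seq}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def concat_supermatrix(
    parts: Sequence[tuple[str, Alignment]]
) -> tuple[Alignment, PartitionMap]:
    """Concatenate per-locus alignments over the union of their taxa.

    A taxon absent from a locus is padded with '?' across that locus's
    columns, the standard supermatrix convention.
    """
    if not parts:
        raise ValueError("need at least one locus")
    taxa: list[str] = []
    for _, aln in parts:
        if aln.ncols == 0:
            raise FormatError("zero-column locus in supermatrix")
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    blocks = []
    intervals = []
    pos = 0
    for name, aln in parts:
        block = np.full((len(taxa), aln.ncols), "?", dtype="<U1")
        idx = {t: i for i, t in enumerate(aln.taxa)}
        for i, t in enumerate(taxa):
            if t in idx:
                block[i] = aln.data[idx[t]]
        blocks.append(block)
        intervals.append((name, pos, pos + aln.ncols))
        pos += aln.ncols
    return Alignment(taxa, np.hstack(blocks)), PartitionMap(intervals)


def subset_taxa(aln: Alignment, keep: Iterable[str]) -> Alignment:
    """Row-subset preserving original row order; columns untouched."""
    keep = set(keep)
    if not keep:
        raise ValueError("empty taxon subset")
    unknown = sorted(keep - set(aln.taxa))
    if unknown:
        raise ValueError(f"taxa not in alignment: {unknown}")
    sel = [i for i, t in enumerate(aln.taxa) if t in keep]
    return Alignment([aln.taxa[i] for i in sel], aln.data[sel].copy())


def extract_locus(aln: Alignment, pmap: PartitionMap, name: str) -> Alignment:
    for n, s, e in pmap.loci:
        if n == name:
            return Alignment(list(aln.taxa), aln.data[:, s:e].copy())
    raise KeyError(name)


# -------------------------------------------------------------------- trees


def read_trees(path: str | Path, format: str = "newick") -> list[Tree]:
    schema = {"newick": "newick", "nexus": "nexus"}[format]
    try:
        tl = dendropy.TreeList.get(path=str(path), schema=schema, preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"cannot parse trees from {path}: {exc}") from exc
    return [
        Tree.from_newick(t.as_string(schema="newick", suppress_rooting=True))
        for t in tl
    ]


def write_trees(trees: Iterable[Tree], path: str | Path, lengths: bool = False) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick(lengths=lengths) + "\n")


def parse_tree(newick: str, rooted: bool | None = None) -> Tree:
    try:
        return Tree.from_newick(newick, rooted=rooted)
    except Exception as exc:
        raise FormatError(f"cannot parse newick: {exc}") from exc
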