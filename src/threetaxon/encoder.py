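"""Williams–Siebert three-taxon-statement (3TS) encoding of DNA matrices.

Each aligned column is polarized against the operational outgroup state and
recoded once per derived nucleotide: taxa carrying the derived state score 1,
taxa demonstrably lacking it score 0, everything else is missing.  Every
such binary presence/absence column expands into the set of minimal
relational claims ij|k — "i and j share the derived state to the exclusion
of k" — one statement per pair of 1-taxa and each 0-taxon.  The union over
columns, with identical statements merged and counted (uniform weight 1 per
occurrence), is the 3TS matrix.

Expanded to explicit binary columns, every statement column carries exactly
two 1s and two 0s (the excluded taxon and the implicit all-plesiomorphic
outgroup row), so every column is parsimony-informative by construction.

The zeros convention is switchable: ``absence`` (default) lets k range over
all scored taxa lacking the derived state, including taxa with a different
derived state; ``plesiomorphic`` restricts k to taxa carrying the outgroup
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .consensus import NUCLEOTIDES
from .io import Alignment

__all__ = [
    "Recoding",
    "TripletStatement",
    "TSMatrix",
    "polarize_column",
    "enumerate_statements",
    "encode_matrix",
    "write_expanded_nexus",
    "write_statements_tsv",
]

OUTGROUP_LABEL = "OP_OUTGROUP"


@dataclass(frozen=True)
class Recoding:
    """One binary presence/absence recoding of a column."""

    derived_state: str
    ones: tuple[int, ...]   # taxon indices carrying the derived state
    zeros: tuple[int, ...]  # taxon indices scored 0 under the active convention

    @property
    def n_statements(self) -> int:
        n1, n0 = len(self.ones), len(self.zeros)
        return n1 * (n1 - 1) // 2 * n0


@dataclass
class TripletStatement:
    """ij|k with per-occurrence provenance; multiplicity = len(provenance)."""

    i: int
    j: int
    k: int
    provenance: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("statement requires i < j")
        if self.k in (self.i, self.j):
            raise ValueError("excluded taxon coincides with the pair")

    @property
    def multiplicity(self) -> int:
        return len(self.provenance)


@dataclass
class TSMatrix:
    """Deduplicated 3TS multiset over an ingroup taxon list.

    The operational outgroup is an implicit all-zero row named
    ``outgroup_label``; it never appears inside a statement.
    """

    taxa: list[str]
    statements: list[TripletStatement]
    outgroup_label: str = OUTGROUP_LABEL

    @property
    def n_statements(self) -> int:
        return sum(s.multiplicity for s in self.statements)

    @property
    def n_distinct(self) -> int:
        return len(self.statements)

    def all_taxa(self) -> list[str]:
        return list(self.taxa) + [self.outgroup_label]

    def expanded_columns(self) -> Iterator[tuple[int, int, int]]:
        """(i, j, k) once per occurrence — the explicit binary matrix,
        streamed column by column, never materialized."""
        for s in self.statements:
            for _ in range(s.multiplicity):
                yield (s.i, s.j, s.k)


def polarize_column(
    column: Sequence[str],
    outgroup_state: str,
    zeros: str = "absence",
) -> list[Recoding]:
    """Binary recodings of one column, one per derived nucleotide present.

    Taxa with gap, '?', 'N' or a partial ambiguity code are unscored
    (missing) in every recoding.
    """
    if outgroup_state not in NUCLEOTIDES:
        raise ValueError(
            f"outgroup state must be one of {NUCLEOTIDES}, got {outgroup_state!r}"
        )
    if zeros not in ("absence", "plesiomorphic"):
        raise ValueError(f"zeros must be 'absence' or 'plesiomorphic', got {zeros!r}")
    scored: dict[str, list[int]] = {nt: [] for nt in NUCLEOTIDES}
    for idx, sym in enumerate(column):
        if sym in scored:
            scored[sym].append(idx)
    out = []
    for nt in NUCLEOTIDES:
        if nt == outgroup_state or not scored[nt]:
            continue
        ones = tuple(scored[nt])
        if zeros == "absence":
            zero_set = tuple(
                sorted(i for s, idxs in scored.items() if s != nt for i in idxs)
            )
        else:
            zero_set = tuple(scored[outgroup_state])
        out.append(Recoding(nt, ones, zero_set))
    return out


def enumerate_statements(recoding: Recoding) -> list[tuple[int, int, int]]:
    """All ij|k of one recoding: pairs of 1-taxa against each 0-taxon."""
    ones = sorted(recoding.ones)
    out = []
    for a in range(len(ones)):
        for b in range(a + 1, len(ones)):
            for k in recoding.zeros:
                out.append((ones[a], ones[b], k))
    return out


def encode_matrix(
    aln: Alignment,
    outgroup_seq: str | Sequence[str],
    zeros: str = "absence",
    outgroup_label: str = OUTGROUP_LABEL,
) -> TSMatrix:
    """3TS matrix of an alignment polarized by an operational outgroup row.

    Columns whose outgroup state is not a plain nucleotide carry no polarity
    and contribute nothing.  Identical statements from different columns are
    merged; each occurrence keeps weight 1 (uniform weighting), recorded in
    the statement's provenance.
    """
    outgroup_seq = "".join(outgroup_seq)
    if len(outgroup_seq) != aln.ncols:
        raise ValueError(
            f"outgroup length {len(outgroup_seq)} != alignment columns {aln.ncols}"
        )
    agg: dict[tuple[int, int, int], list[tuple[int, str]]] = {}
    data = aln.data
    for col in range(aln.ncols):
        og = outgroup_seq[col]
        if og not in NUCLEOTIDES:
            continue
        for rec in polarize_column(data[:, col], og, zeros=zeros):
            n1 = len(rec.ones)
            if n1 < 2 or not rec.zeros:
                continue
            ones = sorted(rec.ones)
            tag = (col, rec.derived_state)
            for a in range(n1):
                ia = ones[a]
                for b in range(a + 1, n1):
                    ib = ones[b]
                    for k in rec.zeros:
                        agg.setdefault((ia, ib, k), []).append(tag)
    statements = [
        TripletStatement(i, j, k, prov)
        for (i, j, k), prov in sorted(agg.items())
    ]
    return TSMatrix(list(aln.taxa), statements, outgroup_label=outgroup_label)


# ----------------------------------------------------------------- exports


def write_expanded_nexus(ts: TSMatrix, path: str | Path) -> None:
    """Expanded binary matrix as NEXUS (SYMBOLS="01" MISSING=?), one column
    per statement occurrence, including the all-zero outgroup row.

    Written column-block by column-block so external parsimony programs see
    the uniform weighting literally without the matrix living in memory.
    """
    taxa = ts.all_taxa()
    n = len(taxa)
    ncols = ts.n_statements
    og_row = n - 1
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={n} NCHAR={ncols};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? INTERLEAVE;\n  MATRIX\n')
        width = max(len(t) for t in taxa) + 2
        chunk = 5000
        cols_iter = ts.expanded_columns()
        written = 0

        def flush(block):
            for t, cells in zip(taxa, block):
                fh.write(f"    {t:<{width}}{''.join(cells)}\n")
            fh.write("\n")

        block = [[] for _ in range(n)]
        for (i, j, k) in cols_iter:
            for r in range(n):
                block[r].append("?")
            block[i][-1] = "1"
            block[j][-1] = "1"
            block[k][-1] = "0"
            block[og_row][-1] = "0"
            written += 1
            if written % chunk == 0:
                flush(block)
                block = [[] for _ in range(n)]
        if block[0]:
            flush(block)
        fh.write("  ;\nEND;\n")


def write_statements_tsv(ts: TSMatrix, path: str | Path) -> None:
    """Deduplicated statements: taxon labels, multiplicity, provenance."""
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tmultiplicity\tprovenance\n")
        for s in ts.statements:
            prov = ";".join(f"{col}:{state}" for col, state in s.provenance)
            fh.write(
                f"{ts.taxa[s.i]}\t{ts.taxa[s.j]}\t{ts.taxa[s.k]}\t"
                f"{s.multiplicity}\t{prov}\n"
            )
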