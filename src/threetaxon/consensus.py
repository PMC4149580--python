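"""Operational outgroup construction by majority-rule sequence consensus.

The three-taxon encoding needs a single all-plesiomorphic reference row.
Following standard practice it is built as the 50% majority-rule consensus
of a designated set of outgroup taxa: a column contributes a state only if
its modal applicable state is unique and reaches the frequency threshold,
otherwise the consensus carries '?' and the column is skipped by the
encoder (no polarity can be assigned).

"Applicable" states are the four nucleotides.  Gap '-', '?' and 'N' never
count; partial IUPAC ambiguities are excluded by default, or split
fractionally among their nucleotides with ``ambiguity="fractional"``.
"""

from __future__ import annotations

import numpy as np

from .io import Alignment, STATE_MASKS

NUCLEOTIDES = "ACGT"

_FRACTIONAL_WEIGHTS: dict[str, dict[str, float]] = {}
for sym, mask in STATE_MASKS.items():
    if sym in "N-?":
        continue
    members = [nt for i, nt in enumerate(NUCLEOTIDES) if mask >> i & 1]
    _FRACTIONAL_WEIGHTS[sym] = {nt: 1.0 / len(members) for nt in members}


def column_profile(
    aln: Alignment,
    taxa: set[str] | list[str],
    col: int,
    ambiguity: str = "skip",
) -> dict[str, float]:
    """Applicable-state frequencies of one column over the given taxa.

    Returns an empty mapping when no taxon shows an applicable state.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    unknown = taxa - set(aln.taxa)
    if unknown:
        raise ValueError(f"taxa not in alignment: {sorted(unknown)}")
    if not 0 <= col < aln.ncols:
        raise IndexError(f"column {col} out of range [0, {aln.ncols})")
    if ambiguity not in ("skip", "fractional"):
        raise ValueError(f"ambiguity must be 'skip' or 'fractional', got {ambiguity!r}")

    counts = {nt: 0.0 for nt in NUCLEOTIDES}
    total = 0.0
    rows = [i for i, t in enumerate(aln.taxa) if t in taxa]
    for i in rows:
        sym = aln.data[i, col]
        if sym in NUCLEOTIDES:
            counts[sym] += 1.0
            total += 1.0
        elif ambiguity == "fractional" and sym in _FRACTIONAL_WEIGHTS and sym not in NUCLEOTIDES:
            for nt, w in _FRACTIONAL_WEIGHTS[sym].items():
                counts[nt] += w
            total += 1.0
    if total == 0:
        return {}
    return {nt: c / total for nt, c in counts.items() if c > 0}


def consensus_sequence(
    aln: Alignment,
    taxa: set[str] | list[str],
    threshold: float = 0.5,
    ambiguity: str = "skip",
) -> str:
    """Majority-rule consensus row: unique mode with frequency >= threshold,
    '?' on no-data columns, sub-threshold modes, and ties."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = []
    for col in range(aln.ncols):
        profile = column_profile(aln, taxa, col, ambiguity=ambiguity)
        if not profile:
            out.append("?")
            continue
        top = max(profile.values())
        modes = [nt for nt, f in profile.items() if f == top]
        if len(modes) == 1 and top >= threshold:
            out.append(modes[0])
        else:
            out.append("?")
    return "".join(out)


def append_consensus_row(
    aln: Alignment,
    taxa: set[str] | list[str],
    label: str = "OP_OUTGROUP",
    threshold: float = 0.5,
    ambiguity: str = "skip",
) -> Alignment:
    """Alignment with the consensus appended as a new terminal row."""
    if label in aln.taxa:
        raise ValueError(f"label {label!r} already present")
    seq = consensus_sequence(aln, taxa, threshold=threshold, ambiguity=ambiguity)
    data = np.vstack([aln.data, np.array(list(seq), dtype="<U1")])
    return Alignment(list(aln.taxa) + [label], data)
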