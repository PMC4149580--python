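#!/usr/bin/env python
"""Simulate the study-shaped supermatrix every later stage analyzes.

Generates a 24-taxon (22 ingroup + 2 outgroup), 10-locus, ~6000-column
supermatrix under Jukes–Cantor on a pure-birth tree, with per-taxon locus
dropout and short gap runs — the shape of a multi-locus plastid supermatrix.
Bulk data go to scratch/, a small summary table to results/.
"""

import json
from pathlib import Path

from threetaxon import SimConfig, simulate_supermatrix, write_alignment, write_trees

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 2024

CONFIG = SimConfig(
    n_taxa=24,
    n_loci=10,
    locus_lengths=(400, 450, 500, 550, 600, 600, 650, 700, 750, 800),
    missing_locus_prob=0.15,
    outgroup_taxa=2,
    seed=SEED,
)


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    tree, aln, pmap = simulate_supermatrix(CONFIG)
    write_alignment(aln, SCRATCH / "supermatrix.fasta")
    write_trees([tree], SCRATCH / "true_tree.nwk", lengths=True)
    with open(SCRATCH / "partitions.tsv", "w") as fh:
        fh.write("locus\tstart\tend\n")
        for name, s, e in pmap.loci:
            fh.write(f"{name}\t{s}\t{e}\n")
    missing = float((aln.data == "?").mean())
    gapped = float((aln.data == "-").mean())
    summary = {
        "seed": SEED,
        "taxa": aln.ntaxa,
        "columns": aln.ncols,
        "loci": len(pmap.loci),
        "missing_fraction": round(missing, 4),
        "gap_fraction": round(gapped, 4),
    }
    (RESULTS / "01_simulation.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"supermatrix: {aln.ntaxa} taxa x {aln.ncols} columns "
          f"({missing:.1%} missing, {gapped:.2%} gaps) -> scratch/analysis/")


if __name__ == "__main__":
    main()
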