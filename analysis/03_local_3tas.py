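#!/usr/bin/env python
"""Local three-taxon analyses inside clades of the global topology.

Two complementary clades are read off the global 3TA tree; each is
re-encoded against the majority-rule consensus of its sister group (its
clade-specific operational outgroup) and searched separately.  Where a
search returns several optimal trees both the strict consensus and the RF
median are produced; the median, unlike the strict consensus, is itself a
minimal-distance summary.
"""

import json
from pathlib import Path

from threetaxon import read_alignment, read_trees, run_local_3tas, write_trees
from threetaxon.pipeline import RunManifest
from threetaxon.trees import _leaves_under

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 177
OUTGROUPS = {"og1", "og2"}


def pick_clades(tree, lo=6, hi=16):
    """The two largest disjoint ingroup clades within the size window."""
    rooted = tree.root_with_outgroup("OP_OUTGROUP")
    chosen = []
    used: set[str] = set()
    nodes = sorted(
        (n for n in rooted.postorder() if not n.is_leaf),
        key=lambda n: -len(_leaves_under(n)),
    )
    for node in nodes:
        leaves = {l.label for l in _leaves_under(node)}
        if "OP_OUTGROUP" in leaves or not lo <= len(leaves) <= hi:
            continue
        if leaves & used:
            continue
        chosen.append(leaves)
        used |= leaves
        if len(chosen) == 2:
            break
    return chosen


def main():
    aln = read_alignment(SCRATCH / "supermatrix.fasta", "fasta")
    global_best = read_trees(SCRATCH / "global_best.nwk")[0]
    ingroup = [t for t in aln.taxa if t not in OUTGROUPS]
    clades = pick_clades(global_best)
    defs = []
    for i, members in enumerate(clades):
        sister = [t for t in ingroup if t not in members]
        defs.append((f"clade{i + 1}", sorted(members), sorted(sister)))

    manifest = RunManifest(config={"stage": "local", "seed": SEED})
    results = run_local_3tas(aln, defs, seed=SEED, manifest=manifest,
                             n_addition_replicates=3, max_trees_per_replicate=50)
    table = {}
    for name, res in results.items():
        n, L = res.ts.n_statements, res.search.length
        write_trees(res.search.best_trees, SCRATCH / f"local_{name}.nwk")
        write_trees([res.minimal_ingroup_tree()], SCRATCH / f"local_{name}.minimal.nwk")
        table[name] = {
            "taxa": len(res.ts.taxa),
            "n_statements": n,
            "length": L,
            "violations": L - n,
            "ri": round(res.search.ri, 4),
            "n_best_trees": len(res.search.best_trees),
            "median_score": res.median_score,
        }
        print(f"{name}: {len(res.ts.taxa)} taxa, N={n}, L={L}, "
              f"RI={res.search.ri:.4f}, {len(res.search.best_trees)} optimal tree(s)"
              + (f", median score {res.median_score}" if res.median_score is not None else ""))
    manifest.write(SCRATCH / "local_manifest.json")
    (RESULTS / "03_local_3tas.json").write_text(json.dumps(table, indent=2) + "\n")


if __name__ == "__main__":
    main()
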