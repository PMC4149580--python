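#!/usr/bin/env python
"""Combine the global and local minimal topologies into one RF supertree.

The global minimal tree spans the full ingroup while the locals span
overlapping subsets; the RF supertree minimizes the summed Robinson-Foulds
distance between each input and the supertree restricted to that input's
leaves.  A score of 0 means the supertree displays every input exactly.
"""

import json
from pathlib import Path

from threetaxon import combine, read_alignment, read_trees, rf_distance, write_trees
from threetaxon.pipeline import RunManifest
from threetaxon.parsimony import _normalize_unrooted
from threetaxon.trees import prune_leaves

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main():
    inputs = []
    names = []
    glob = read_trees(SCRATCH / "global_best.nwk")[0]
    glob = prune_leaves(glob.root_with_outgroup("OP_OUTGROUP"), ["OP_OUTGROUP"])
    glob.rooted = True
    inputs.append(glob)
    names.append("global")
    for p in sorted(SCRATCH.glob("local_*.minimal.nwk")):
        t = read_trees(p)[0]
        t.rooted = True
        inputs.append(t)
        names.append(p.stem.replace(".minimal", ""))

    manifest = RunManifest(config={"stage": "combine", "inputs": names})
    supertree, score = combine(inputs, manifest=manifest, mode="rooted")
    write_trees([supertree], SCRATCH / "supertree.nwk")
    manifest.record_file("combine", SCRATCH / "supertree.nwk")
    manifest.write(SCRATCH / "combine_manifest.json")

    truth = read_trees(SCRATCH / "true_tree.nwk")[0]
    truth_in = prune_leaves(truth, ["og1", "og2"])
    truth_in.rooted = False
    _normalize_unrooted(truth_in)
    st_u = supertree.copy()
    st_u.rooted = False
    _normalize_unrooted(st_u)
    rf_truth = rf_distance(st_u, truth_in, mode="unrooted")
    out = {
        "inputs": names,
        "supertree_score": score,
        "rf_to_generating_topology": rf_truth,
        "supertree": supertree.newick(),
    }
    (RESULTS / "04_supertree.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"RF supertree of {len(inputs)} inputs: score={score}, "
          f"RF to generating topology={rf_truth}")


if __name__ == "__main__":
    main()
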