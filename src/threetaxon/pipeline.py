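"""Staged three-taxon-analysis workflow and its run manifest.

The global stage reduces the supermatrix to a working taxon set, builds the
operational outgroup as a majority-rule consensus of designated outgroup
taxa, encodes the matrix into three-taxon statements, and runs a parsimony
search on them.  Local stages repeat the encode-and-search cycle inside
user-defined clades, each polarized by its own consensus outgroup
(typically the sister group); where a search returns several optimal trees
both the strict consensus and the RF median are produced.  Finally all
minimal topologies are combined into a single RF supertree.

Clade definitions are explicit taxon lists supplied by the user, not
auto-detected: clade choice is an analytical decision made by inspecting
the global topology.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .consensus import consensus_sequence
from .encoder import TSMatrix, encode_matrix
from .io import Alignment, subset_taxa
from .parsimony import SearchResult, mp_search
from .trees import Tree
from .treecompare import rf_median, rf_supertree, strict_consensus

__all__ = ["RunManifest", "StageRecord", "run_global_3ta", "run_local_3tas", "combine"]


@dataclass
class StageRecord:
    name: str
    stats: dict
    outputs: dict = field(default_factory=dict)  # filename -> sha256


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)

    def add_stage(self, name: str, stats: dict, outputs: dict | None = None) -> None:
        self.stages.append(StageRecord(name, stats, outputs or {}))

    def record_file(self, stage: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        for s in self.stages:
            if s.name == stage:
                s.outputs[str(path)] = digest
                return
        raise KeyError(stage)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "stages": [
                    {"name": s.name, "stats": s.stats, "outputs": s.outputs}
                    for s in self.stages
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class TaResult:
    """One three-taxon analysis: encoding plus its search."""

    ts: TSMatrix
    search: SearchResult
    consensus_outgroup: str
    strict: Tree | None = None
    median: Tree | None = None
    median_score: int | None = None

    @property
    def minimal_tree(self) -> Tree:
        """The stage's representative minimal topology: the single optimum,
        or the RF median of the optima (itself of minimal length when the
        strict consensus is not)."""
        if len(self.search.best_trees) == 1:
            return self.search.best_trees[0]
        return self.median

    def minimal_ingroup_tree(self) -> Tree:
        """Minimal topology rooted by — and then stripped of — the
        operational outgroup, ready for cross-stage combination."""
        t = self.minimal_tree
        og = self.ts.outgroup_label
        if og in set(t.leaf_labels()):
            t = t.root_with_outgroup(og)
            t.root.children = [c for c in t.root.children if c.label != og]
            inner = t.root.children[0]
            inner.parent = None
            t = Tree(inner, rooted=True)
        return t


def _analyze(
    aln: Alignment,
    outgroup_taxa: Sequence[str],
    seed: int,
    ambiguity: str = "skip",
    zeros: str = "absence",
    **search_params,
) -> TaResult:
    og_seq = consensus_sequence(aln, set(outgroup_taxa), ambiguity=ambiguity)
    ingroup = subset_taxa(aln, [t for t in aln.taxa if t not in set(outgroup_taxa)])
    ts = encode_matrix(ingroup, og_seq, zeros=zeros)
    search = mp_search(ts, seed=seed, **search_params)
    result = TaResult(ts, search, og_seq)
    if len(search.best_trees) > 1:
        rooted = [
            t.root_with_outgroup(ts.outgroup_label) for t in search.best_trees
        ]
        result.strict = strict_consensus(rooted)
        result.median, result.median_score = rf_median(rooted)
    return result


def run_global_3ta(
    supermatrix: Alignment,
    outgroup_taxa: Sequence[str],
    keep_taxa: Sequence[str] | None = None,
    seed: int = 0,
    manifest: RunManifest | None = None,
    **search_params,
) -> TaResult:
    """Reduce -> consensus outgroup -> encode -> search, with manifest stats."""
    missing = [t for t in outgroup_taxa if t not in supermatrix.taxa]
    if missing:
        raise ValueError(f"outgroup taxa not in matrix: {missing}")
    aln = supermatrix
    if keep_taxa is not None:
        aln = subset_taxa(aln, set(keep_taxa) | set(outgroup_taxa))
    result = _analyze(aln, outgroup_taxa, seed, **search_params)
    if manifest is not None:
        n = result.ts.n_statements
        L = result.search.length
        manifest.seeds["global"] = seed
        manifest.add_stage(
            "global_3ta",
            {
                "taxa": len(result.ts.taxa),
                "n_statements": n,
                "length": L,
                "violations": L - n,
                "ri": result.search.ri,
                "n_best_trees": len(result.search.best_trees),
            },
        )
    return result


def run_local_3tas(
    supermatrix: Alignment,
    clades: Sequence[tuple[str, Sequence[str], Sequence[str]]],
    seed: int = 0,
    manifest: RunManifest | None = None,
    **search_params,
) -> dict[str, TaResult]:
    """Per-clade 3TAs: (name, clade taxa, outgroup taxa) triples.

    Each clade is encoded against the majority-rule consensus of its own
    outgroup expression (the nesting inside such expressions carries no
    computational weight — the consensus is flat over the listed taxa).
    """
    out: dict[str, TaResult] = {}
    for idx, (name, members, og_taxa) in enumerate(clades):
        if not members:
            raise ValueError(f"clade {name!r} is empty")
        aln = subset_taxa(supermatrix, set(members) | set(og_taxa))
        result = _analyze(aln, og_taxa, seed + idx, **search_params)
        out[name] = result
        if manifest is not None:
            n = result.ts.n_statements
            L = result.search.length
            manifest.seeds[f"local:{name}"] = seed + idx
            manifest.add_stage(
                f"local_3ta:{name}",
                {
                    "taxa": len(result.ts.taxa),
                    "n_statements": n,
                    "length": L,
                    "violations": L - n,
                    "ri": result.search.ri,
                    "n_best_trees": len(result.search.best_trees),
                    "median_score": result.median_score,
                },
            )
    return out


def combine(
    trees: Sequence[Tree],
    manifest: RunManifest | None = None,
    mode: str | None = None,
) -> tuple[Tree, int]:
    """RF supertree of the collected minimal topologies."""
    if len(trees) < 1:
        raise ValueError("nothing to combine")
    if len(trees) == 1:
        supertree, score = trees[0].copy(), 0
    else:
        supertree, score = rf_supertree(trees, mode=mode)
    if manifest is not None:
        manifest.add_stage(
            "combine",
            {"n_inputs": len(trees), "supertree_score": score},
        )
    return supertree, score
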