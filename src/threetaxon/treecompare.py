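"""Robinson–Foulds distances, consensus trees, RF medians and supertrees.

Two comparison modes: ``rooted`` compares cluster sets (clades), ``unrooted``
compares bipartition sets.  The default, chosen per call when mode is None,
is rooted when every input carries a root, unrooted otherwise — the
workflow's trees are rooted by their operational outgroups.

The RF median uses the fact that a majority-rule consensus minimizes the
summed symmetric-difference distance to the profile: a split present in
more than half the inputs lowers the sum when included, one below half
raises it, and one at exactly half is neutral.  Majority splits are always
mutually compatible, so the optimum is constructed directly; neutral 50%
splits are then added greedily (most frequent first, deterministic order)
to honour the prefer-resolution tie-break.

The RF supertree over overlapping leaf sets minimizes the summed RF between
each input and the supertree pruned to that input's leaves.  Exhaustive
enumeration (including multifurcations) is used for small leaf unions; a
backbone + greedy leaf insertion + local refinement heuristic beyond.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from .trees import (
    Tree,
    all_topologies,
    all_unrooted_topologies,
    all_rooted_topologies,
    tree_from_clusters,
    tree_from_splits,
)

__all__ = [
    "rf_distance",
    "strict_consensus",
    "majority_consensus",
    "rf_median",
    "rf_supertree",
    "restrict_tree",
]

#: exhaustive-search cutoffs (leaf-union sizes); full enumeration of all
#: topologies including multifurcations is feasible up to 10395 binary
#: shapes, i.e. 8 unrooted or 7 rooted leaves
EXACT_MEDIAN_LEAVES = 7
EXACT_SUPERTREE_LEAVES = {"unrooted": 8, "rooted": 7}


def _resolve_mode(trees: Sequence[Tree], mode: str | None) -> str:
    if mode is None:
        return "rooted" if all(t.rooted for t in trees) else "unrooted"
    if mode not in ("rooted", "unrooted"):
        raise ValueError(f"mode must be rooted|unrooted, got {mode!r}")
    return mode


def _groups(tree: Tree, mode: str) -> set[frozenset[str]]:
    return tree.clusters() if mode == "rooted" else tree.splits()


def rf_distance(t1: Tree, t2: Tree, mode: str | None = None) -> int:
    """Symmetric difference of cluster (rooted) or bipartition (unrooted)
    sets; both trees must carry identical leaf sets."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ (restrict first): only-left={sorted(l1 - l2)}, "
            f"only-right={sorted(l2 - l1)}"
        )
    mode = _resolve_mode((t1, t2), mode)
    return len(_groups(t1, mode) ^ _groups(t2, mode))


# ---------------------------------------------------------------- consensus


def _build(labels: list[str], groups: Iterable[frozenset[str]], mode: str) -> Tree:
    if mode == "rooted":
        return tree_from_clusters(labels, groups, rooted=True)
    return tree_from_splits(labels, groups)


def _check_same_leaves(trees: Sequence[Tree]) -> list[str]:
    if not trees:
        raise ValueError("need at least one tree")
    labels = set(trees[0].leaf_labels())
    for t in trees[1:]:
        if set(t.leaf_labels()) != labels:
            raise ValueError("trees carry different leaf sets")
    return sorted(labels)


def strict_consensus(trees: Sequence[Tree], mode: str | None = None) -> Tree:
    """Tree of the groups present in every input."""
    labels = _check_same_leaves(trees)
    mode = _resolve_mode(trees, mode)
    common = set.intersection(*(_groups(t, mode) for t in trees))
    return _build(labels, common, mode)


def majority_consensus(
    trees: Sequence[Tree], threshold: float = 0.5, mode: str | None = None
) -> Tree:
    """Tree of the groups present in more than ``threshold`` of the inputs
    (a group at exactly the threshold is excluded)."""
    if not 0.5 <= threshold < 1:
        raise ValueError("threshold must be in [0.5, 1)")
    labels = _check_same_leaves(trees)
    mode = _resolve_mode(trees, mode)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for g in _groups(t, mode):
            counts[g] = counts.get(g, 0) + 1
    keep = [g for g, c in counts.items() if c > threshold * len(trees)]
    return _build(labels, keep, mode)


# --------------------------------------------------------------- RF median


def _compatible(a: frozenset[str], b: frozenset[str], labels: frozenset[str], mode: str) -> bool:
    if mode == "rooted":
        return a <= b or b <= a or not (a & b)
    # unrooted splits in canonical form (side without the reference leaf):
    # compatible iff nested, disjoint, or jointly covering
    return a <= b or b <= a or not (a & b) or (a | b) == labels


def _score_against(tree: Tree, inputs: Sequence[Tree], mode: str) -> int:
    g = _groups(tree, mode)
    return sum(len(g ^ _groups(t, mode)) for t in inputs)


def rf_median(
    trees: Sequence[Tree], mode: str | None = None
) -> tuple[Tree, int]:
    """Median tree minimizing the summed RF distance to the inputs.

    Among equal-score optima, prefers the most resolved tree, breaking
    remaining ties by frequency and then lexicographic group order.
    """
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    labels = _check_same_leaves(trees)
    mode = _resolve_mode(trees, mode)
    full = frozenset(labels)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for g in _groups(t, mode):
            counts[g] = counts.get(g, 0) + 1
    n = len(trees)
    majority = [g for g, c in counts.items() if 2 * c > n]
    chosen = list(majority)
    # score-neutral groups (exactly half the inputs): add while compatible,
    # most frequent semantics are all tied here so order lexicographically
    neutral = sorted(
        (g for g, c in counts.items() if 2 * c == n),
        key=lambda g: (-len(g), sorted(g)),
    )
    for g in neutral:
        if all(_compatible(g, h, full, mode) for h in chosen):
            chosen.append(g)
    median = _build(labels, chosen, mode)
    return median, _score_against(median, trees, mode)


def rf_median_exhaustive(
    trees: Sequence[Tree], mode: str | None = None
) -> tuple[Tree, int]:
    """Brute-force median over all topologies (small leaf sets only)."""
    labels = _check_same_leaves(trees)
    mode = _resolve_mode(trees, mode)
    if len(labels) > EXACT_MEDIAN_LEAVES:
        raise ValueError("exhaustive median limited to small leaf sets")
    best, best_score = None, None
    for cand in all_topologies(labels, rooted=(mode == "rooted")):
        cand.rooted = mode == "rooted"
        s = _score_against(cand, trees, mode)
        if best_score is None or s < best_score:
            best, best_score = cand, s
    return best, best_score


# ------------------------------------------------------------ RF supertree


def restrict_tree(tree: Tree, keep: Iterable[str], mode: str) -> set[frozenset[str]]:
    """Group set of a tree pruned to a leaf subset, computed directly on the
    group sets (no tree surgery needed)."""
    keep = frozenset(keep)
    out: set[frozenset[str]] = set()
    if mode == "rooted":
        for cl in tree.clusters():
            r = cl & keep
            if 1 < len(r) < len(keep):
                out.add(r)
    else:
        ref = min(keep)
        labels = frozenset(tree.leaf_labels())
        for side in tree.splits():
            other = labels - side
            r = side & keep
            if ref in r:
                r = keep - r
            if 1 < len(r) < len(keep) - 1:
                out.add(r)
    return out


def _restrict_group(
    group: frozenset[str], leaves: frozenset[str], mode: str
) -> frozenset[str] | None:
    if mode == "rooted":
        r = group & leaves
        return r if 1 < len(r) < len(leaves) else None
    r = group & leaves
    if min(leaves) in r:
        r = leaves - r
    return r if 1 < len(r) < len(leaves) - 1 else None


class _SupertreeScorer:
    """Summed RF between a candidate group set (restricted per input) and
    the inputs, with per-group restrictions memoized."""

    def __init__(
        self,
        inputs: Sequence[tuple[frozenset[str], set[frozenset[str]]]],
        mode: str,
    ):
        self.inputs = inputs
        self.mode = mode
        self._memo: list[dict[frozenset[str], frozenset[str] | None]] = [
            {} for _ in inputs
        ]

    def __call__(self, groups: Iterable[frozenset[str]]) -> int:
        total = 0
        for (leaves, in_groups), memo in zip(self.inputs, self._memo):
            restricted = set()
            for g in groups:
                r = memo.get(g, _MISSING)
                if r is _MISSING:
                    r = _restrict_group(g, leaves, self.mode)
                    memo[g] = r
                if r is not None:
                    restricted.add(r)
            total += len(restricted ^ in_groups)
        return total


_MISSING = object()


def _supertree_score(
    groups: set[frozenset[str]],
    union: frozenset[str],
    inputs: Sequence[tuple[frozenset[str], set[frozenset[str]]]],
    mode: str,
) -> int:
    return _SupertreeScorer(inputs, mode)(groups)


def _overlap_connected(leaf_sets: list[frozenset[str]]) -> bool:
    seen = set([0])
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(len(leaf_sets)):
            if j not in seen and leaf_sets[i] & leaf_sets[j]:
                seen.add(j)
                frontier.append(j)
    return len(seen) == len(leaf_sets)


def rf_supertree(
    trees: Sequence[Tree], mode: str | None = None
) -> tuple[Tree, int]:
    """Supertree minimizing summed RF to the inputs after restriction.

    Exhaustive (binary enumeration plus contraction refinement) for small
    leaf unions; otherwise greedy construction from the largest input with
    leaf insertion and local refinement.  The score is exact for the
    returned tree in either case.
    """
    if not trees:
        raise ValueError("need at least one tree")
    mode = _resolve_mode(trees, mode)
    leaf_sets = [frozenset(t.leaf_labels()) for t in trees]
    if not _overlap_connected(leaf_sets):
        raise ValueError("inputs do not overlap into a connected whole")
    union = frozenset().union(*leaf_sets)
    labels = sorted(union)
    inputs = [
        (ls, _canonical_groups_on(t, ls, mode)) for t, ls in zip(trees, leaf_sets)
    ]
    score_groups = _SupertreeScorer(inputs, mode)

    if len(trees) == 1:
        t = trees[0].copy()
        return t, 0

    if len(union) <= EXACT_SUPERTREE_LEAVES[mode]:
        best_groups, best_score = _exhaustive_supertree(labels, score_groups, mode)
    else:
        best_groups, best_score = _greedy_supertree(
            trees, leaf_sets, labels, score_groups, mode
        )
    tree = _build(labels, best_groups, mode)
    tree.rooted = mode == "rooted"
    return tree, best_score


def _canonical_groups_on(tree: Tree, leaves: frozenset[str], mode: str) -> set[frozenset[str]]:
    if mode == "rooted":
        return tree.clusters()
    return tree.splits()


def _contraction_refine(groups: set[frozenset[str]], score_groups) -> tuple[set, int]:
    """Greedy first-improvement over single-group deletions."""
    current = set(groups)
    score = score_groups(current)
    improved = True
    while improved:
        improved = False
        for g in sorted(current, key=lambda g: (len(g), sorted(g))):
            cand = current - {g}
            s = score_groups(cand)
            if s < score:
                current, score = cand, s
                improved = True
                break
    return current, score


def _exhaustive_supertree(labels, score_groups, mode) -> tuple[set, int]:
    """Minimum over every topology on ``labels``: each binary shape plus all
    contractions of its internal edges, deduplicated by group set."""
    gen = (
        all_rooted_topologies(list(labels))
        if mode == "rooted"
        else all_unrooted_topologies(list(labels))
    )
    best_groups, best_score = set(), score_groups(set())
    seen: set[frozenset[frozenset[str]]] = {frozenset()}
    for cand in gen:
        base = list(cand.clusters() if mode == "rooted" else cand.splits())
        for r in range(1, len(base) + 1):
            for sub in itertools.combinations(base, r):
                key = frozenset(sub)
                if key in seen:
                    continue
                seen.add(key)
                s = score_groups(key)
                if s < best_score:
                    best_groups, best_score = set(key), s
    return best_groups, best_score


def _greedy_supertree(trees, leaf_sets, labels, score_groups, mode) -> tuple[set, int]:
    order = sorted(range(len(trees)), key=lambda i: -len(leaf_sets[i]))
    backbone = trees[order[0]]
    placed = set(leaf_sets[order[0]])
    groups = _canonical_groups_on(backbone, leaf_sets[order[0]], mode)
    groups = set(groups)
    full = frozenset(labels)
    # insert missing leaves one at a time at the position minimizing the score
    missing = [l for l in labels if l not in placed]
    for leaf in missing:
        best = None
        # candidate placements: add the leaf into any existing group (or none)
        current_groups = sorted(groups, key=lambda g: (len(g), sorted(g)))
        options = [set()]
        options += [{g} | {h for h in current_groups if g < h} for g in current_groups]
        for opt in options:
            cand = {(g | {leaf}) if g in opt else g for g in groups}
            s = score_groups(cand)
            if best is None or s < best[1]:
                best = (cand, s)
        groups = best[0]
        placed.add(leaf)
    # local refinement: drop harmful groups, then try adding input-supported ones
    groups, score = _contraction_refine(groups, score_groups)
    candidates: set[frozenset[str]] = set()
    for ls, gset in zip(leaf_sets, [(_canonical_groups_on(t, ls, mode)) for t, ls in zip(trees, leaf_sets)]):
        candidates |= gset
    improved = True
    while improved:
        improved = False
        for g in sorted(candidates, key=lambda g: (len(g), sorted(g))):
            if g in groups:
                continue
            if all(_compatible(g, h, full, mode) for h in groups):
                cand = groups | {g}
                s = score_groups(cand)
                if s < score:
                    groups, score = cand, s
                    improved = True
    return groups, score
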