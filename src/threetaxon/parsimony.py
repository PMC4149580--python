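"""Parsimony lengths, heuristic/exact searches, and ensemble statistics.

Two kinds of matrix are scored:

* conventional DNA alignments, under unordered (Fitch) parsimony with IUPAC
  ambiguity codes as partial state sets and gap/'?' as fully missing;
* three-taxon-statement matrices, where a statement ij|k costs 1 step when
  the tree rooted at the operational outgroup accommodates it (the i+j
  ancestor lies strictly below the i+j+k ancestor) and 2 steps otherwise.
  Total length is therefore N + V with N statements and V violations, and
  the ensemble retention index collapses to the closed form (2N - L)/N.

Column scoring is a unit-cost dynamic program over the four nucleotide
states, exact on polytomies and on set-valued (ambiguous/missing) leaves,
vectorized across columns with site-pattern compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .encoder import TSMatrix, TripletStatement
from .io import Alignment, STATE_MASKS
from .trees import (
    Node,
    Tree,
    all_unrooted_topologies,
    num_unrooted_topologies,
)

__all__ = [
    "CharacterStats",
    "SearchResult",
    "fitch_length",
    "ts_length",
    "char_stats",
    "ensemble_ci_ri",
    "ensemble_stats_3ts",
    "mp_search",
    "exact_search",
    "jackknife",
]

_BIG = np.int32(1 << 20)


# ------------------------------------------------------------ column DP


def _leaf_costs(masks: np.ndarray) -> np.ndarray:
    """(4, ncols) unit costs for a leaf given its state-set bitmasks."""
    bits = ((masks[None, :] >> np.arange(4)[:, None]) & 1).astype(bool)
    return np.where(bits, np.int32(0), _BIG)


def _dp_column_lengths(tree: Tree, mask_rows: Mapping[str, np.ndarray]) -> np.ndarray:
    """Minimum steps per column: unit-cost Sankoff over {A,C,G,T}."""
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                m = mask_rows[node.label]
            except KeyError:
                raise ValueError(f"leaf {node.label!r} has no character row") from None
            costs[id(node)] = _leaf_costs(np.asarray(m, dtype=np.uint8))
        else:
            acc = None
            for ch in node.children:
                cc = costs.pop(id(ch))
                contrib = np.minimum(cc, cc.min(axis=0) + np.int32(1))
                acc = contrib if acc is None else acc + contrib
            costs[id(node)] = acc
    return costs[id(tree.root)].min(axis=0).astype(np.int64)


def fitch_length(tree: Tree, column: Mapping[str, str]) -> int:
    """Minimum state changes of one column on a tree (polytomies allowed).

    ``column`` maps taxon label to symbol; '?'/'-'/'N' act as the full state
    set, partial IUPAC codes as partial sets.
    """
    symbol_masks = dict(STATE_MASKS)
    symbol_masks.update({"0": 1, "1": 2})  # binary characters ride two states
    rows = {}
    for leaf in tree.leaves():
        if leaf.label not in column:
            raise ValueError(f"leaf {leaf.label!r} has no character row")
        sym = column[leaf.label].upper()
        if sym not in symbol_masks:
            raise ValueError(f"invalid symbol {sym!r} for taxon {leaf.label!r}")
        rows[leaf.label] = np.array([symbol_masks[sym]], dtype=np.uint8)
    return int(_dp_column_lengths(tree, rows)[0])


# ---------------------------------------------------------- DNA scorer


class DnaScorer:
    """Alignment length scorer with site-pattern compression."""

    def __init__(self, aln: Alignment):
        self.alignment = aln
        self.taxa = list(aln.taxa)
        masks = aln.masks()
        patterns, self._col_to_pattern, counts = np.unique(
            masks, axis=1, return_inverse=True, return_counts=True
        )
        self._patterns = patterns  # (ntaxa, npatterns)
        self._weights = counts.astype(np.int64)
        self._row_index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def kind(self) -> str:
        return "dna"

    def score(self, tree: Tree) -> int:
        rows = {
            leaf.label: self._patterns[self._row_index[leaf.label]]
            for leaf in tree.leaves()
        }
        steps = _dp_column_lengths(tree, rows)
        return int(steps @ self._weights)

    def per_column_steps(self, tree: Tree) -> np.ndarray:
        rows = {
            leaf.label: self._patterns[self._row_index[leaf.label]]
            for leaf in tree.leaves()
        }
        return _dp_column_lengths(tree, rows)[self._col_to_pattern]


# ----------------------------------------------------------- 3TS scorer


class TsScorer:
    """Statement-matrix scorer by the ancestor (MRCA) accommodation rule."""

    def __init__(self, ts: TSMatrix):
        self.ts = ts
        self.outgroup = ts.outgroup_label
        self.taxa = list(ts.taxa) + [self.outgroup]
        self._n_ingroup = len(ts.taxa)
        pair_ks: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for s in ts.statements:
            pair_ks.setdefault((s.i, s.j), []).append((s.k, s.multiplicity))
        self._pairs = [
            (i, j, np.array([k for k, _ in lst]), np.array([m for _, m in lst]))
            for (i, j), lst in sorted(pair_ks.items())
        ]
        self._restrict_cache: dict[frozenset[int], tuple] = {}

    @property
    def kind(self) -> str:
        return "3ts"

    def _restricted(self, present: frozenset[int]):
        got = self._restrict_cache.get(present)
        if got is None:
            pairs = []
            n_present = 0
            for i, j, ks, mult in self._pairs:
                if i in present and j in present:
                    sel = np.isin(ks, list(present))
                    if sel.any():
                        pairs.append((i, j, ks[sel], mult[sel]))
                        n_present += int(mult[sel].sum())
            got = (pairs, n_present)
            self._restrict_cache[present] = got
        return got

    def length_and_violations(self, tree: Tree) -> tuple[int, int]:
        """(length, violations) of a tree containing the outgroup leaf (any
        rooting) or already rooted on the ingroup."""
        labels = set(tree.leaf_labels())
        if self.outgroup in labels:
            rooted = tree.root_with_outgroup(self.outgroup)
            ingroup_root = next(
                c for c in rooted.root.children if c.label != self.outgroup
            )
        elif tree.rooted:
            ingroup_root = tree.root
        else:
            raise ValueError(
                "3TS scoring needs the operational outgroup leaf or a rooted tree"
            )
        n = self._n_ingroup
        idx = {t: i for i, t in enumerate(self.ts.taxa)}
        member: dict[int, np.ndarray] = {}
        leaf_node: dict[int, Node] = {}
        order = []
        stack = [(ingroup_root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                order.append(node)
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in node.children)
        for node in order:
            if node.is_leaf:
                v = np.zeros(n, dtype=bool)
                ti = idx.get(node.label)
                if ti is None:
                    raise ValueError(f"leaf {node.label!r} not a statement taxon")
                v[ti] = True
                member[id(node)] = v
                leaf_node[ti] = node
            else:
                member[id(node)] = np.logical_or.reduce(
                    [member[id(c)] for c in node.children]
                )

        present = frozenset(leaf_node)
        pairs, n_present = self._restricted(present)
        violations = 0
        for i, j, ks, mult in pairs:
            node = leaf_node[i]
            while not member[id(node)][j]:
                node = node.parent
            cluster = member[id(node)]
            violations += int(mult[cluster[ks]].sum())
        return n_present + violations, violations

    def score(self, tree: Tree) -> int:
        return self.length_and_violations(tree)[0]


def ts_length(tree: Tree, ts: TSMatrix) -> tuple[int, int]:
    """Length and violation count of a 3TS matrix on a tree.

    A statement ij|k is accommodated iff the ancestor of {i, j} is a proper
    descendant of the ancestor of {i, j, k} once the tree is rooted at the
    operational outgroup; accommodated statements cost 1 step, violated
    ones 2, so length = N + V.
    """
    return TsScorer(ts).length_and_violations(tree)


# ------------------------------------------------------------ statistics


@dataclass
class CharacterStats:
    """Per-character observed steps s, minimum m, and maximum g."""

    steps: np.ndarray
    min_steps: np.ndarray
    max_steps: np.ndarray

    @property
    def length(self) -> int:
        return int(self.steps.sum())


def char_stats(matrix: Alignment | TSMatrix, tree: Tree) -> CharacterStats:
    """s/m/g per character on a scored tree.

    For DNA columns m = (#observed nucleotide states - 1) and
    g = (#nucleotide-scored taxa) - (largest state class); ambiguity codes
    and gaps count as missing for m and g.  For 3TS matrices every
    occurrence has m = 1, g = 2 by construction.
    """
    if isinstance(matrix, TSMatrix):
        n = matrix.n_statements
        length, v = ts_length(tree, matrix)
        steps = np.ones(n, dtype=np.int64)
        steps[:v] = 2  # per-character attribution is order-free in the ensemble
        return CharacterStats(steps, np.ones(n, np.int64), np.full(n, 2, np.int64))
    masks = matrix.masks()
    nuc = np.zeros((4, matrix.ncols), dtype=np.int64)
    for b, mask in enumerate((1, 2, 4, 8)):
        nuc[b] = (masks == mask).sum(axis=0)
    observed = (nuc > 0).sum(axis=0)
    m = np.maximum(observed - 1, 0)
    g = nuc.sum(axis=0) - nuc.max(axis=0)
    s = DnaScorer(matrix).per_column_steps(tree)
    return CharacterStats(s, m, g)


def ensemble_ci_ri(stats: CharacterStats) -> tuple[float, float]:
    """CI = sum(m)/L, RI = (sum(g) - L)/(sum(g) - sum(m)).

    RI is NaN when every character is uninformative (sum g == sum m).
    """
    L = stats.length
    sm = int(stats.min_steps.sum())
    sg = int(stats.max_steps.sum())
    ci = sm / L if L else math.nan
    ri = (sg - L) / (sg - sm) if sg != sm else math.nan
    return ci, ri


def ensemble_stats_3ts(n_statements: int, length: int) -> tuple[float, float]:
    """Closed-form ensemble (CI, RI) of a uniform-weight 3TS matrix.

    Every statement has minimum 1 and maximum 2 steps, so
    CI = N/L and RI = (2N - L)/N without materializing any columns.
    """
    if n_statements <= 0:
        raise ValueError("need at least one statement")
    return n_statements / length, (2 * n_statements - length) / n_statements


# ----------------------------------------------------------------- search


@dataclass
class SearchResult:
    best_trees: list[Tree]
    length: int
    ci: float
    ri: float
    seed: int | None
    n_replicates: int
    params: dict = field(default_factory=dict)

    @property
    def best_tree(self) -> Tree:
        return self.best_trees[0]


def make_scorer(matrix: Alignment | TSMatrix):
    return TsScorer(matrix) if isinstance(matrix, TSMatrix) else DnaScorer(matrix)


def _normalize_unrooted(tree: Tree) -> Tree:
    """Keep the representation a valid unrooted tree (root degree >= 3
    where possible, no unifurcations)."""
    tree.suppress_unifurcations()
    while len(tree.root.children) == 2 and not all(
        c.is_leaf for c in tree.root.children
    ):
        a, b = tree.root.children
        keep = a if not a.is_leaf else b
        move = b if keep is a else a
        tree.root.children = []
        for c in list(keep.children):
            tree.root.add(c)
        tree.root.add(move)
    return tree


def _attachable_edges(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _insert_at_edge(tree: Tree, edge_child: Node, sub: Node) -> None:
    parent = edge_child.parent
    mid = Node()
    i = parent.children.index(edge_child)
    parent.children[i] = mid
    mid.parent = parent
    mid.add(edge_child)
    mid.add(sub)


def _detach(tree: Tree, node: Node) -> None:
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if parent.parent is None and len(parent.children) == 1:
        only = parent.children[0]
        only.parent = None
        tree.root = only
    _normalize_unrooted(tree)


def _stepwise_addition(scorer, order: list[str], rng: np.random.Generator) -> Tree:
    root = Node()
    for lab in order[:3]:
        root.add(Node(lab))
    tree = Tree(root, rooted=False)
    for lab in order[3:]:
        best: list[tuple[Tree, int]] = []
        best_len = None
        for ei in range(len(_attachable_edges(tree))):
            cand = tree.copy()
            _insert_at_edge(cand, _attachable_edges(cand)[ei], Node(lab))
            ln = scorer.score(cand)
            if best_len is None or ln < best_len:
                best, best_len = [cand], ln
            elif ln == best_len:
                best.append(cand)
        tree = best[int(rng.integers(len(best)))]
    return tree


def _node_by_path(tree: Tree, path: tuple[int, ...]) -> Node:
    node = tree.root
    for i in path:
        node = node.children[i]
    return node


def _paths(tree: Tree) -> list[tuple[int, ...]]:
    out = []

    def rec(node: Node, path: tuple[int, ...]):
        for i, c in enumerate(node.children):
            out.append(path + (i,))
            rec(c, path + (i,))

    rec(tree.root, ())
    return out


def _spr_neighbors(tree: Tree, reroot_cap: int = 1):
    """Yield SPR rearrangements; ``reroot_cap`` > 1 additionally reroots the
    pruned subtree at its internal edges (TBR-style reconnection) for
    subtrees of at most ``reroot_cap`` leaves."""
    from .trees import _leaves_under

    nleaves = len(tree.leaves())
    for path in _paths(tree):
        probe = _node_by_path(tree, path)
        if len(_leaves_under(probe)) >= nleaves - 2:
            continue  # too little left to reattach to
        base = tree.copy()
        sub = _node_by_path(base, path)
        _detach(base, sub)
        sub_variants = [sub]
        if reroot_cap > 1 and not sub.is_leaf and len(_leaves_under(sub)) <= reroot_cap:
            subtree = Tree(sub, rooted=False)
            # TBR-style reconnection: re-hang the pruned clade by each of its
            # pendant edges before regrafting
            for lab in [l.label for l in subtree.leaves()][1:]:
                rr = subtree.copy().root_with_outgroup(lab)
                sub_variants.append(rr.root)
        for variant in sub_variants:
            for ei in range(len(_attachable_edges(base))):
                cand = base.copy()
                vcopy = Tree(variant, rooted=False).copy().root
                _insert_at_edge(cand, _attachable_edges(cand)[ei], vcopy)
                yield cand


def _nni_neighbors(tree: Tree):
    for path in _paths(tree):
        node = _node_by_path(tree, path)
        if node.is_leaf or node.parent is None:
            continue
        parent = node.parent
        for ci in range(len(node.children)):
            for si, sib in enumerate(parent.children):
                if sib is node:
                    continue
                cand = tree.copy()
                cnode = _node_by_path(cand, path)
                cparent = cnode.parent
                a = cnode.children[ci]
                b = cparent.children[si]
                cnode.children[ci] = b
                b.parent = cnode
                cparent.children[si] = a
                a.parent = cparent
                yield cand


def _neighbors(tree: Tree, swap: str, full_tbr: bool = False):
    if swap == "nni":
        yield from _nni_neighbors(tree)
    elif swap == "spr":
        yield from _spr_neighbors(tree, reroot_cap=1)
    elif swap == "tbr":
        cap = 10**9 if full_tbr else 8
        yield from _spr_neighbors(tree, reroot_cap=cap)
    else:
        raise ValueError(f"swap must be nni|spr|tbr, got {swap!r}")


def _swap_to_optimum(
    tree: Tree, scorer, swap: str, max_trees: int, full_tbr: bool = False
) -> tuple[dict, int]:
    best_len = scorer.score(tree)
    pool = {tree.topology_key(): tree}
    queue = [tree]
    while queue:
        current = queue.pop()
        for cand in _neighbors(current, swap, full_tbr):
            key = cand.topology_key()
            ln = scorer.score(cand)
            if ln < best_len:
                best_len = ln
                pool = {key: cand}
                queue = [cand]
                break
            if ln == best_len and key not in pool and len(pool) < max_trees:
                pool[key] = cand
                queue.append(cand)
    return pool, best_len


def _result_stats(matrix, best_tree: Tree, length: int) -> tuple[float, float]:
    if isinstance(matrix, TSMatrix):
        return ensemble_stats_3ts(matrix.n_statements, length)
    return ensemble_ci_ri(char_stats(matrix, best_tree))


def _finalize(matrix, pool: dict, length: int, seed, reps, params) -> SearchResult:
    trees = sorted(pool.values(), key=lambda t: t.canonical_newick())
    ci, ri = _result_stats(matrix, trees[0], length)
    return SearchResult(trees, length, ci, ri, seed, reps, params)


def mp_search(
    matrix: Alignment | TSMatrix,
    n_addition_replicates: int = 10,
    max_trees_per_replicate: int = 100,
    swap: str = "tbr",
    seed: int | None = None,
    max_trees_total: int = 1000,
    full_tbr: bool = False,
) -> SearchResult:
    """Heuristic parsimony search: random-addition starting trees followed
    by branch swapping, pooling equally optimal distinct topologies.

    Deterministic under a fixed seed.  Binary statement characters are
    scored as ordered (Wagner) parsimony, which coincides with unordered
    scoring for two states.
    """
    if n_addition_replicates < 1 or max_trees_per_replicate < 1:
        raise ValueError("replicate and tree caps must be positive")
    scorer = make_scorer(matrix)
    taxa = list(scorer.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    best_len = None
    pool: dict = {}
    og = scorer.outgroup if isinstance(scorer, TsScorer) else None
    for _ in range(n_addition_replicates):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        if og is not None:
            # every partial tree must contain the outgroup so it can be scored
            order.remove(og)
            order.insert(0, og)
        start = _stepwise_addition(scorer, order, rng)
        rep_pool, rep_len = _swap_to_optimum(
            start, scorer, swap, max_trees_per_replicate, full_tbr
        )
        if best_len is None or rep_len < best_len:
            best_len = rep_len
            pool = dict(rep_pool)
        elif rep_len == best_len:
            for k, v in rep_pool.items():
                if k not in pool and len(pool) < max_trees_total:
                    pool[k] = v
    params = {
        "n_addition_replicates": n_addition_replicates,
        "max_trees_per_replicate": max_trees_per_replicate,
        "swap": swap,
        "full_tbr": full_tbr,
    }
    return _finalize(matrix, pool, best_len, seed, n_addition_replicates, params)


def exact_search(
    matrix: Alignment | TSMatrix, max_trees: int | None = None
) -> SearchResult:
    """Global optimum by exhaustive enumeration of unrooted topologies.

    Intended as an oracle at small sizes; refuses more than 9 leaves
    (10395 topologies at 8, 135135 at 9) — use :func:`mp_search` beyond.
    """
    scorer = make_scorer(matrix)
    taxa = list(scorer.taxa)
    if len(taxa) > 9:
        raise ValueError(
            f"{len(taxa)} taxa: {num_unrooted_topologies(len(taxa))} topologies "
            "is beyond exact enumeration; use mp_search"
        )
    best_len = None
    pool: dict = {}
    for t in all_unrooted_topologies(taxa):
        ln = scorer.score(t)
        if best_len is None or ln < best_len:
            best_len = ln
            pool = {t.topology_key(): t}
        elif ln == best_len and (max_trees is None or len(pool) < max_trees):
            pool.setdefault(t.topology_key(), t)
    return _finalize(matrix, pool, best_len, None, 0, {"method": "exact"})


# -------------------------------------------------------------- jackknife


def _delete_characters(
    matrix: Alignment | TSMatrix, fraction: float, rng: np.random.Generator
):
    if isinstance(matrix, TSMatrix):
        mult = np.array([s.multiplicity for s in matrix.statements])
        total = int(mult.sum())
        keep_n = total - round(fraction * total)
        kept = rng.multivariate_hypergeometric(mult, keep_n)
        statements = [
            TripletStatement(s.i, s.j, s.k, s.provenance[:m])
            for s, m in zip(matrix.statements, kept)
            if m > 0
        ]
        return TSMatrix(list(matrix.taxa), statements, matrix.outgroup_label)
    ncols = matrix.ncols
    n_del = round(fraction * ncols)
    keep = np.sort(rng.choice(ncols, size=ncols - n_del, replace=False))
    return Alignment(list(matrix.taxa), matrix.data[:, keep].copy())


def jackknife(
    matrix: Alignment | TSMatrix,
    reps: int = 100,
    delete_fraction: float = 0.37,
    seed: int | None = None,
    **search_params,
) -> dict[frozenset[str], float]:
    """Character-jackknife clade support.

    Each replicate deletes ``round(fraction * ncols)`` characters without
    replacement, reruns the search, and records the splits of the
    replicate's strict consensus; support is the percentage of replicates
    containing each split.
    """
    if not 0 <= delete_fraction < 1:
        raise ValueError("delete_fraction must be in [0, 1)")
    from .treecompare import strict_consensus

    rng = np.random.default_rng(seed)
    search_params.setdefault("n_addition_replicates", 2)
    search_params.setdefault("max_trees_per_replicate", 20)
    counts: dict[frozenset[str], int] = {}
    for _ in range(reps):
        sub = _delete_characters(matrix, delete_fraction, rng)
        res = mp_search(sub, seed=int(rng.integers(2**31)), **search_params)
        cons = strict_consensus(res.best_trees)
        for split in cons.splits():
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / reps for split, c in counts.items()}
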