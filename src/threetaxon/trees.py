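"""Lightweight phylogenetic tree container and topology operations.

Trees here are plain rooted node structures with an ``rooted`` flag deciding
whether cluster (rooted) or split (unrooted) semantics apply downstream.
Polytomies are first-class: internal nodes may have any number >= 2 of
children.  Branch lengths are carried but ignored by all parsimony code.

Newick parsing is delegated to dendropy; writing is a direct recursion over
this structure so polytomies and rooting survive a round trip unchanged.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Tree",
    "all_unrooted_topologies",
    "all_rooted_topologies",
    "num_unrooted_topologies",
]


class Node:
    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)} children>)"


class Tree:
    """Rooted node structure; ``rooted=False`` marks unrooted semantics."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dn) -> Node:
            node = Node(
                label=dn.taxon.label.replace(" ", "_") if dn.taxon is not None else None,
                length=dn.edge.length,
            )
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        root = convert(dt.seed_node)
        if rooted is None:
            # no explicit marker: a basal bifurcation conventionally means rooted
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def newick(self, lengths: bool = False) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return rec(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick(lengths=True),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    # ------------------------------------------------------------ traversal

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        need = 2 if self.rooted else 3
        nodes = self.internal_nodes()
        for n in nodes:
            k = len(n.children)
            if n is self.root:
                if k != need:
                    return False
            elif k != 2:
                return False
        return True

    # ----------------------------------------------------------- structure

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root), rooted=self.rooted)

    def suppress_unifurcations(self) -> None:
        """Collapse nodes with a single child (in place)."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        if node.length is not None and child.length is not None:
                            child.length += node.length
                        self.root = child
                    else:
                        parent = node.parent
                        i = parent.children.index(node)
                        parent.children[i] = child
                        child.parent = parent
                        if node.length is not None and child.length is not None:
                            child.length += node.length
                    changed = True
                    break

    # --------------------------------------------------- clusters & splits

    def clusters(self, trivial: bool = False) -> set[frozenset[str]]:
        """Leaf clusters of internal edges (rooted semantics)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        all_leaves: frozenset[str] | None = None
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = cl
                if node is self.root:
                    all_leaves = cl
                else:
                    out.add(cl)
        if trivial:
            out |= {frozenset([l]) for l in (all_leaves or frozenset())}
            if all_leaves:
                out.add(all_leaves)
        return out

    def splits(self, trivial: bool = False) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side that does
        not contain the lexicographically smallest leaf (unrooted semantics)."""
        labels = frozenset(self.leaf_labels())
        ref = min(labels)
        out: set[frozenset[str]] = set()
        for cl in self.clusters(trivial=trivial):
            side = cl if ref not in cl else labels - cl
            if trivial or 1 < len(side) < len(labels) - 1:
                if side:
                    out.add(side)
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable identity: clusters if rooted, splits otherwise."""
        return frozenset(self.clusters() if self.rooted else self.splits())

    def canonical_newick(self) -> str:
        def key(node: Node):
            return min(l.label for l in _leaves_under(node))

        def rec(node: Node) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(rec(c) for c in sorted(node.children, key=key)) + ")"

        return rec(self.root) + ";"

    # ------------------------------------------------------------- rooting

    def root_with_outgroup(self, label: str) -> "Tree":
        """Return a copy rooted on the pendant edge of leaf ``label``.

        The result has a bifurcating root with the outgroup leaf as one child
        and the remainder of the tree as the other.
        """
        t = self.copy()
        target = None
        for n in t.postorder():
            if n.is_leaf and n.label == label:
                target = n
                break
        if target is None:
            raise ValueError(f"outgroup leaf {label!r} not in tree")
        if target.parent is t.root and len(t.root.children) == 2:
            t.rooted = True
            return t
        # reorient: walk from target's parent up to the old root, reversing
        path = []
        n = target.parent
        while n is not None:
            path.append(n)
            n = n.parent
        for i in range(len(path) - 1, 0, -1):
            upper, lower = path[i], path[i - 1]
            upper.children.remove(lower)
            lower.add(upper)
        base = path[0]
        base.children.remove(target)
        base.parent = None
        new_root = Node()
        new_root.add(target)
        new_root.add(base)
        out = Tree(new_root, rooted=True)
        out.suppress_unifurcations()
        # suppress may have replaced base if it went unary; root stays binary
        return out

    def unroot(self) -> "Tree":
        """Return an unrooted copy (basal bifurcation collapsed to trifurcation)."""
        t = self.copy()
        t.rooted = False
        if len(t.root.children) == 2:
            a, b = t.root.children
            keep, move = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                return t  # two-leaf tree, nothing to collapse
            t.root.children = []
            for c in list(keep.children):
                t.root.add(c)
            t.root.add(move)
        return t


def prune_leaves(tree: Tree, drop: Iterable[str]) -> Tree:
    """Copy of the tree with the named leaves removed and any resulting
    unlabelled leaves / unifurcations suppressed."""
    drop = set(drop)
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder()):
            dead_leaf = node.is_leaf and (node.label in drop or node.label is None)
            if dead_leaf and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
    t.suppress_unifurcations()
    return t


def _leaves_under(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


# ---------------------------------------------------------------- builders


def tree_from_clusters(
    labels: Iterable[str], clusters: Iterable[frozenset[str]], rooted: bool = True
) -> Tree:
    """Build a tree realizing a nested (pairwise compatible) cluster set."""
    labels = list(labels)
    nontrivial = [c for c in set(map(frozenset, clusters)) if 1 < len(c) < len(labels)]
    nontrivial.sort(key=len, reverse=True)
    root = Node()
    holder: dict[frozenset[str], Node] = {frozenset(labels): root}
    order = [frozenset(labels)] + nontrivial
    for cl in nontrivial:
        parent = None
        best = None
        for cand in order:
            if cl < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent = holder[best]
        node = Node()
        parent.add(node)
        holder[cl] = node
    for lab in labels:
        best = None
        for cand in order:
            if lab in cand and (best is None or len(cand) < len(best)):
                best = cand
        holder[best].add(Node(lab))
    return Tree(root, rooted=rooted)


def tree_from_splits(labels: Iterable[str], splits: Iterable[frozenset[str]]) -> Tree:
    """Build an unrooted tree realizing a compatible split set.

    Splits are given in the canonical form of :meth:`Tree.splits` (the side
    not containing the smallest leaf).
    """
    labels = list(labels)
    return tree_from_clusters(labels, splits, rooted=False)


# ------------------------------------------------------------- enumeration


def num_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — binary unrooted topologies on n labelled leaves."""
    out = 1
    for k in range(4, n + 1):
        out *= 2 * k - 5
    return out


def all_unrooted_topologies(labels: list[str]) -> Iterator[Tree]:
    """All binary unrooted topologies by sequential leaf insertion."""
    labels = list(labels)
    if len(labels) < 3:
        root = Node()
        for l in labels:
            root.add(Node(l))
        yield Tree(root, rooted=False)
        return

    def build(k: int, edges_choice: list[int]) -> Tree:
        root = Node()
        for l in labels[:3]:
            root.add(Node(l))
        t = Tree(root, rooted=False)
        for idx, lab in zip(edges_choice, labels[3:]):
            edges = _edges(t)
            child = edges[idx]
            parent = child.parent
            mid = Node()
            i = parent.children.index(child)
            parent.children[i] = mid
            mid.parent = parent
            mid.add(child)
            mid.add(Node(lab))
        return t

    n_extra = len(labels) - 3
    ranges = [range(2 * k + 3) for k in range(n_extra)]  # edges before k-th insertion: 3,5,7,..
    for choice in itertools.product(*ranges):
        yield build(len(labels), list(choice))


def _edges(t: Tree) -> list[Node]:
    """Edges identified by their child node, in deterministic order."""
    return [n for n in t.postorder() if n.parent is not None]


def all_rooted_topologies(labels: list[str]) -> Iterator[Tree]:
    """All binary rooted topologies = unrooted topologies on labels + handle."""
    handle = "\x00root"
    for t in all_unrooted_topologies([handle] + list(labels)):
        rt = t.root_with_outgroup(handle)
        # drop the handle leaf
        rt.root.children = [c for c in rt.root.children if c.label != handle]
        inner = rt.root.children[0]
        inner.parent = None
        yield Tree(inner, rooted=True)


def all_topologies(labels: list[str], rooted: bool = False) -> Iterator[Tree]:
    """All topologies including multifurcating ones, without duplicates.

    Generated as the contraction closure of the binary topologies; intended
    for small leaf sets (oracle-scale exhaustive searches).
    """
    seen: set[frozenset[frozenset[str]]] = set()
    gen = all_rooted_topologies(labels) if rooted else all_unrooted_topologies(labels)
    for t in gen:
        base = t.clusters() if rooted else t.splits()
        base = list(base)
        for r in range(len(base) + 1):
            for sub in itertools.combinations(base, r):
                key = frozenset(sub)
                if key in seen:
                    continue
                seen.add(key)
                if rooted:
                    yield tree_from_clusters(labels, sub, rooted=True)
                else:
                    yield tree_from_splits(labels, sub)
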