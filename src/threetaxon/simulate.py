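"""Synthetic multi-locus supermatrices with the structure the workflow assumes.

The generator emulates the shape of a plastid supermatrix study: a rooted
pure-birth ingroup phylogeny with one or more basally attached outgroup
taxa, roughly ten loci of unequal length evolved independently under
Jukes–Cantor, per-taxon locus dropout padded as missing, and short gap runs
injected into otherwise clean alignments.  It produces exactly the objects
the pipeline consumes (Alignment + PartitionMap + true Tree), so every
stage is testable without any sequence download.

All randomness flows from one seed through named per-stage generators, so
each stage's output is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import Alignment, PartitionMap, concat_supermatrix
from .trees import Node, Tree

__all__ = ["SimConfig", "simulate_tree", "evolve_sequences", "simulate_supermatrix", "fixture_toys"]

NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-shaped defaults: tens of taxa, ~10 loci, kilobases of columns."""

    n_taxa: int = 40
    n_loci: int = 10
    locus_lengths: tuple[int, ...] | None = None  # default: 400..1200 spread
    birth_rate: float = 1.0
    substitution_rates: tuple[float, ...] | None = None  # per locus, subst/site/unit depth
    missing_locus_prob: float = 0.15
    gap_rate: float = 0.002  # gap-run starts per site
    gap_mean_len: float = 4.0
    outgroup_taxa: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0 <= self.missing_locus_prob <= 1:
            raise ValueError("missing_locus_prob must be a probability")
        if self.birth_rate < 0 or self.gap_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.locus_lengths is None:
            # unequal lengths as in multi-locus plastid data, total ~ n_loci*800
            lens = np.linspace(400, 1200, self.n_loci).round().astype(int)
            self.locus_lengths = tuple(int(x) for x in lens)
        if len(self.locus_lengths) != self.n_loci:
            raise ValueError("one length per locus required")
        if self.substitution_rates is None:
            self.substitution_rates = tuple(
                0.05 + 0.10 * i / max(self.n_loci - 1, 1) for i in range(self.n_loci)
            )
        if len(self.substitution_rates) != self.n_loci:
            raise ValueError("one substitution rate per locus required")
        if any(r < 0 for r in self.substitution_rates):
            raise ValueError("rates must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        return _stage_rng(self.seed, stage)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    # hash() is salted per process; derive stage offsets stably instead
    offset = sum(ord(c) * 131**i for i, c in enumerate(stage)) % (2**31)
    return np.random.default_rng([seed, offset])


def simulate_tree(config: SimConfig) -> Tree:
    """Pure-birth rooted binary ingroup tree with outgroups attached basally.

    Branch lengths are Yule waiting times (expected depth ~ ln(n)/birth
    rate); substitution rates multiply these lengths, so at the default
    birth rate of 1 a rate of 0.1 yields roughly 0.2-0.3 substitutions per
    site along a root-to-tip path.
    """
    rng = _stage_rng(config.seed, "tree")
    n_in = config.n_taxa - config.outgroup_taxa
    if n_in < 3:
        raise ValueError("need at least 3 ingroup taxa")
    bd = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=n_in,
        rng=_PyRandom(rng),
    )
    for i, leaf in enumerate(bd.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:03d}"
    ingroup = Tree.from_newick(
        bd.as_string(schema="newick", suppress_rooting=True), rooted=True
    )
    # natural Yule branch lengths: expected depth ~ ln(n)/birth_rate, so a
    # faster birth rate shortens branches; outgroup stems scale with depth
    depth = _max_depth(ingroup.root) or 1.0
    root = Node()
    stem = Node(length=0.3 * depth)
    for c in list(ingroup.root.children):
        stem.add(c)
    root.add(stem)
    for j in range(config.outgroup_taxa):
        root.add(Node(f"og{j + 1}", length=depth * (0.5 + 0.25 * j)))
    return Tree(root, rooted=True)


class _PyRandom:
    """Adapter exposing the stdlib-random surface dendropy expects."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def random(self):
        return float(self._rng.random())

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma)) if sigma else float(mu)


def _max_depth(node: Node, acc: float = 0.0) -> float:
    if node.is_leaf:
        return acc
    return max(_max_depth(c, acc + (c.length or 0.0)) for c in node.children)


def _jc_evolve(tree: Tree, length: int, rate: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Jukes–Cantor evolution of integer-coded sequences down a tree."""
    seqs: dict[int, np.ndarray] = {id(tree.root): rng.integers(0, 4, size=length)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            parent_seq = seqs[id(node.parent)]
            t = (node.length or 0.0) * rate
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            seq = parent_seq.copy()
            hit = rng.random(length) < p_change
            if hit.any():
                # draw uniformly among the three other states
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            seqs[id(node)] = seq
        if node.is_leaf:
            out[node.label] = seqs[id(node)]
    return out


def evolve_sequences(tree: Tree, config: SimConfig) -> tuple[Alignment, PartitionMap]:
    """Per-locus JC evolution, locus dropout as '?', short gap runs, and
    concatenation into a supermatrix.

    Substitution rates are expressed per site across the full ingroup root
    to tip depth, so divergence is rate-controlled regardless of the Yule
    tree's absolute time scale.
    """
    labels = tree.leaf_labels()
    parts = []
    depth = _max_depth(tree.root) or 1.0
    rng_drop = _stage_rng(config.seed, "dropout")
    rng_gap = _stage_rng(config.seed, "gaps")
    for li in range(config.n_loci):
        rng = _stage_rng(config.seed, f"locus{li}")
        length = config.locus_lengths[li]
        seqs = _jc_evolve(tree, length, config.substitution_rates[li] / depth, rng)
        data = np.array([NUC[seqs[lab]] for lab in labels], dtype="<U1")
        # gap runs
        if config.gap_rate > 0:
            for r in range(len(labels)):
                starts = np.nonzero(rng_gap.random(length) < config.gap_rate)[0]
                for s in starts:
                    run = 1 + rng_gap.geometric(1.0 / config.gap_mean_len)
                    data[r, s : s + run] = "-"
        # locus dropout (outgroup rows excluded so polarity survives)
        for r, lab in enumerate(labels):
            if not lab.startswith("og") and rng_drop.random() < config.missing_locus_prob:
                data[r] = "?"
        parts.append((f"locus_{li + 1:02d}", Alignment(list(labels), data)))
    return concat_supermatrix(parts)


def simulate_supermatrix(config: SimConfig) -> tuple[Tree, Alignment, PartitionMap]:
    tree = simulate_tree(config)
    aln, pmap = evolve_sequences(tree, config)
    return tree, aln, pmap


# ------------------------------------------------------------------ toys


def fixture_toys() -> dict:
    """Hand-built matrices and trees used as oracles across the test suite.

    * ``encoder_toy``: 5-taxon matrix whose statement list is enumerable by
      hand under the absence convention.
    * ``clean_eight``: an 8-taxon zero-homoplasy matrix generated on a known
      tree; every statement is accommodated on it.
    * ``conflict_trees``: small tree sets with known consensus/median
      behaviour.
    """
    from .io import Alignment

    encoder_aln = Alignment(
        ["t1", "t2", "t3", "t4", "t5"],
        np.array(
            [
                list("AA"),
                list("CA"),
                list("CA"),
                list("GA"),
                list("?A"),
            ],
            dtype="<U1",
        ),
    )
    # outgroup state A at both columns; hand enumeration (zeros=absence):
    # col0: s=C ones {t2,t3} zeros {t1,t4} -> (t2,t3|t1), (t2,t3|t4)
    #       s=G ones {t4} -> no pair
    # col1: all A or missing -> nothing
    encoder_expected = {
        (1, 2, 0): 1,  # t2,t3 | t1
        (1, 2, 3): 1,  # t2,t3 | t4
    }

    true8 = Tree.from_newick(
        "(((a,b),(c,d)),((e,f),(g,h)));", rooted=True
    )
    # one diagnostic column per clade: derived state shared by exactly that
    # clade, outgroup state elsewhere -> no homoplasy anywhere
    clades = [
        ("ab", "C"), ("cd", "C"), ("ef", "C"), ("gh", "C"),
        ("abcd", "G"), ("efgh", "G"),
    ]
    labels8 = list("abcdefgh")
    cols = []
    for members, state in clades:
        cols.append([state if l in members else "A" for l in labels8])
    clean8 = Alignment(labels8, np.array(cols, dtype="<U1").T)

    conflict_trees = [
        Tree.from_newick("((a,b),(c,(d,e)));", rooted=True),
        Tree.from_newick("((a,b),((c,d),e));", rooted=True),
        Tree.from_newick("((a,b),(c,(d,e)));", rooted=True),
    ]
    return {
        "encoder_toy": (encoder_aln, "AA", encoder_expected),
        "clean_eight": (true8, clean8, "A" * clean8.ncols),
        "conflict_trees": conflict_trees,
    }
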