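"""RF distances, consensus trees, RF medians and supertrees."""

import itertools

import dendropy
import numpy as np
import pytest

import threetaxon as tt
from threetaxon.treecompare import (
    _SupertreeScorer,
    _canonical_groups_on,
    _score_against,
    rf_median,
    rf_supertree,
)
from threetaxon.trees import all_topologies

from conftest import random_tree


def dendropy_rf(t1, t2):
    """Independent unrooted RF via dendropy's bipartition machinery."""
    tns = dendropy.TaxonNamespace()
    d1 = t1.to_dendropy(tns)
    d2 = t2.to_dendropy(tns)
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


def set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def rooted_multifurcating_cluster_sets(labels):
    """All rooted (every internal node >= 2 children) trees as cluster sets,
    generated recursively by set partitions — independent of the package's
    contraction-closure enumerator."""
    labels = list(labels)
    if len(labels) == 1:
        yield frozenset()
        return
    for part in set_partitions(labels):
        if len(part) < 2:
            continue
        subgens = [list(rooted_multifurcating_cluster_sets(b)) for b in part]
        for combo in itertools.product(*subgens):
            clusters = set()
            for block, sub in zip(part, combo):
                if len(block) > 1:
                    clusters.add(frozenset(block))
                clusters |= sub
            yield frozenset(clusters)


def all_group_sets(labels, mode):
    """Group sets of every topology (binary and multifurcating)."""
    seen = set()
    if mode == "rooted":
        for cs in rooted_multifurcating_cluster_sets(labels):
            key = frozenset(g for g in cs if 1 < len(g) < len(labels))
            if key not in seen:
                seen.add(key)
                yield key
    else:
        for cs in rooted_multifurcating_cluster_sets(sorted(labels)[1:]):
            key = frozenset(g for g in cs if 1 < len(g) < len(labels) - 1)
            if key not in seen:
                seen.add(key)
                yield key


class TestRfDistance:
    def test_identical_zero(self, rng):
        t = random_tree([f"x{i}" for i in range(8)], rng)
        assert tt.rf_distance(t, t.copy(), mode="unrooted") == 0

    def test_one_cherry_swap_is_two(self):
        t1 = tt.parse_tree("((a,b),c,(d,e));", rooted=False)
        t2 = tt.parse_tree("((a,c),b,(d,e));", rooted=False)
        assert tt.rf_distance(t1, t2, mode="unrooted") == 2

    def test_binary_vs_star_counts_internal_edges(self, rng):
        t = random_tree([f"x{i}" for i in range(7)], rng)
        star = tt.parse_tree("(" + ",".join(t.leaf_labels()) + ");", rooted=False)
        assert tt.rf_distance(t, star, mode="unrooted") == len(t.splits())

    def test_leaf_set_mismatch_rejected(self):
        t1 = tt.parse_tree("((a,b),(c,d));")
        t2 = tt.parse_tree("((a,b),(c,e));")
        with pytest.raises(ValueError, match="restrict"):
            tt.rf_distance(t1, t2)

    def test_agrees_with_dendropy(self, rng):
        for _ in range(10):
            labs = [f"x{i}" for i in range(int(rng.integers(5, 12)))]
            t1, t2 = random_tree(labs, rng), random_tree(labs, rng)
            assert tt.rf_distance(t1, t2, mode="unrooted") == dendropy_rf(t1, t2)

    def test_metric_properties(self, rng):
        for mode in ("rooted", "unrooted"):
            labs = [f"x{i}" for i in range(7)]
            ts = [random_tree(labs, rng, rooted=(mode == "rooted")) for _ in range(3)]
            a, b, c = (
                tt.rf_distance(ts[0], ts[1], mode=mode),
                tt.rf_distance(ts[1], ts[2], mode=mode),
                tt.rf_distance(ts[0], ts[2], mode=mode),
            )
            assert a == tt.rf_distance(ts[1], ts[0], mode=mode)
            assert a + b >= c and b + c >= a and a + c >= b


class TestConsensus:
    def test_identical_inputs_returned(self, rng):
        t = random_tree([f"x{i}" for i in range(6)], rng, rooted=True)
        assert tt.strict_consensus([t, t.copy()]).clusters() == t.clusters()

    def test_one_cherry_disagreement_collapses_exactly_it(self):
        t1 = tt.parse_tree("((a,b),(c,(d,e)));")
        t2 = tt.parse_tree("((a,b),((c,d),e));")
        cons = tt.strict_consensus([t1, t2], mode="rooted")
        assert cons.clusters() == {frozenset("ab"), frozenset("cde")}

    def test_majority_two_of_three_retained(self, toys):
        trees = toys["conflict_trees"]
        maj = tt.majority_consensus(trees, mode="rooted")
        assert frozenset("de") in maj.clusters()  # appears 2/3 > 0.5

    def test_strict_subset_of_majority(self, rng):
        labs = [f"x{i}" for i in range(7)]
        trees = [random_tree(labs, rng, rooted=True) for _ in range(4)]
        strict = tt.strict_consensus(trees).clusters()
        maj = tt.majority_consensus(trees).clusters()
        assert strict <= maj

    def test_tie_at_exact_threshold_excluded(self):
        t1 = tt.parse_tree("((a,b),(c,(d,e)));")
        t2 = tt.parse_tree("(((a,b),c),(d,e));")
        maj = tt.majority_consensus([t1, t2], mode="rooted")
        # clades at exactly 1/2 are dropped; only shared ones stay
        assert maj.clusters() == {frozenset("ab"), frozenset("de")}

    def test_agrees_with_dendropy_majority(self, rng):
        labs = [f"x{i}" for i in range(7)]
        trees = [random_tree(labs, rng) for _ in range(5)]
        maj = tt.majority_consensus(trees, mode="unrooted")
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList([t.to_dendropy(tns) for t in trees], taxon_namespace=tns)
        dmaj = tl.consensus(min_freq=0.5000001)
        dmaj_tt = tt.parse_tree(dmaj.as_string(schema="newick", suppress_rooting=True))
        dmaj_tt.rooted = False
        assert tt.rf_distance(maj, dmaj_tt, mode="unrooted") == 0


class TestRfMedian:
    def test_identical_inputs_score_zero(self, rng):
        t = random_tree([f"x{i}" for i in range(6)], rng, rooted=True)
        med, score = tt.rf_median([t, t.copy(), t.copy()])
        assert score == 0
        assert tt.rf_distance(med, t) == 0

    def test_two_inputs_triangle_property(self, rng):
        """With two inputs the minimum achievable score is their distance."""
        for _ in range(5):
            labs = [f"x{i}" for i in range(6)]
            t1, t2 = (random_tree(labs, rng, rooted=True) for _ in range(2))
            med, score = tt.rf_median([t1, t2])
            assert score == tt.rf_distance(t1, t2)

    @pytest.mark.parametrize("mode", ["rooted", "unrooted"])
    def test_matches_exhaustive_minimum(self, rng, mode):
        for _ in range(4):
            nl = int(rng.integers(5, 7))
            labs = [f"x{i}" for i in range(nl)]
            trees = [
                random_tree(labs, rng, rooted=(mode == "rooted"))
                for _ in range(int(rng.integers(2, 5)))
            ]
            med, score = rf_median(trees, mode=mode)
            groups = lambda t: t.clusters() if mode == "rooted" else t.splits()
            brute = min(
                sum(len(gs ^ groups(t)) for t in trees)
                for gs in all_group_sets(labs, mode)
            )
            assert score == brute

    def test_never_worse_than_best_input(self, rng):
        labs = [f"x{i}" for i in range(8)]
        trees = [random_tree(labs, rng, rooted=True) for _ in range(5)]
        _, score = tt.rf_median(trees)
        best_input = min(_score_against(t, trees, "rooted") for t in trees)
        assert score <= best_input

    def test_needs_two_trees(self, rng):
        with pytest.raises(ValueError):
            tt.rf_median([random_tree(list("abcde"), rng, rooted=True)])


class TestRfSupertree:
    def test_single_input_identity(self, rng):
        t = random_tree([f"x{i}" for i in range(6)], rng, rooted=True)
        st, score = tt.rf_supertree([t])
        assert score == 0 and tt.rf_distance(st, t) == 0

    def test_compatible_overlap_scores_zero(self):
        a = tt.parse_tree("((a,b),(c,(d,e)));")
        b = tt.parse_tree("((a,b),(c,(d,(f,g))));")
        st, score = tt.rf_supertree([a, b], mode="rooted")
        assert score == 0
        assert set(st.leaf_labels()) == set("abcdefg")

    def test_nine_leaf_compatible_union_scores_zero(self):
        """Beyond the exhaustive cutoff the heuristic still finds the
        score-0 supertree when the inputs agree on their overlap."""
        a = tt.parse_tree("(((a,b),(c,d)),((e,f),(g,h)));")
        b = tt.parse_tree("(((a,b),(c,i)),(e,f));")
        st, score = tt.rf_supertree([a, b], mode="rooted")
        assert set(st.leaf_labels()) == set("abcdefghi")
        assert score == 0

    def test_disconnected_overlap_rejected(self):
        a = tt.parse_tree("((a,b),(c,d));")
        b = tt.parse_tree("((w,x),(y,z));")
        with pytest.raises(ValueError, match="overlap"):
            tt.rf_supertree([a, b], mode="rooted")

    @pytest.mark.parametrize("mode", ["rooted", "unrooted"])
    def test_matches_exhaustive_minimum(self, rng, mode):
        """Conflicting partial inputs against brute force over all
        topologies on the leaf union."""
        hi = 7 if mode == "rooted" else 8
        for _ in range(3):
            nu = int(rng.integers(6, hi + 1))
            union = [f"x{i}" for i in range(nu)]
            trees = [
                random_tree(
                    sorted(rng.choice(union, size=int(rng.integers(4, nu + 1)), replace=False)),
                    rng,
                    rooted=(mode == "rooted"),
                )
                for _ in range(int(rng.integers(2, 6)))
            ]
            trees.append(random_tree(union, rng, rooted=(mode == "rooted")))
            st, score = rf_supertree(trees, mode=mode)
            leaf_sets = [frozenset(t.leaf_labels()) for t in trees]
            scorer = _SupertreeScorer(
                [(ls, _canonical_groups_on(t, ls, mode)) for t, ls in zip(trees, leaf_sets)],
                mode,
            )
            brute = min(scorer(gs) for gs in all_group_sets(union, mode))
            assert score == brute
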