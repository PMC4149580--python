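"""Parsimony scoring, searches, ensemble statistics, and jackknife."""

import itertools

import numpy as np
import pytest

import threetaxon as tt
from threetaxon.io import Alignment, STATE_MASKS
from threetaxon.parsimony import DnaScorer, char_stats, ensemble_ci_ri
from threetaxon.trees import Node

from conftest import random_alignment, random_tree


def brute_force_column_min(tree, column):
    """Exhaustive minimum over all internal-node state assignments."""
    internal = [n for n in tree.postorder() if not n.is_leaf]
    leaf_sets = {
        id(l): [s for s in range(4) if STATE_MASKS[column[l.label]] >> s & 1]
        for l in tree.leaves()
    }
    best = None
    for assign in itertools.product(range(4), repeat=len(internal)):
        st = {id(n): a for n, a in zip(internal, assign)}
        cost = 0
        for n in tree.postorder():
            if n.parent is None:
                continue
            if n.is_leaf:
                cost += min(0 if s == st[id(n.parent)] else 1 for s in leaf_sets[id(n)])
            else:
                cost += st[id(n)] != st[id(n.parent)]
        if best is None or cost < best:
            best = cost
    return best


class TestFitchLength:
    def test_quartet_one_change(self):
        t = tt.parse_tree("((i,j),(k,og));")
        assert tt.fitch_length(t, {"i": "1", "j": "1", "k": "0", "og": "0"}) == 1

    def test_quartet_two_changes(self):
        t = tt.parse_tree("((i,k),(j,og));")
        assert tt.fitch_length(t, {"i": "1", "j": "1", "k": "0", "og": "0"}) == 2

    def test_missing_leaf_row_errors(self):
        t = tt.parse_tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="'d'"):
            tt.fitch_length(t, {"a": "A", "b": "A", "c": "A"})

    def test_matches_exhaustive_assignment_minimum(self, rng):
        """Random trees (with polytomies), missing data and ambiguity codes
        against brute force over all internal labelings."""
        syms = list("ACGT") + ["?", "-", "R", "Y", "N"]
        for _ in range(25):
            n = int(rng.integers(5, 9))
            labs = [f"t{i}" for i in range(n)]
            t = random_tree(labs, rng)
            if rng.random() < 0.5:  # contract one internal edge -> polytomy
                internals = [
                    x for x in t.postorder() if not x.is_leaf and x.parent is not None
                ]
                if internals:
                    v = internals[int(rng.integers(len(internals)))]
                    p = v.parent
                    p.children.remove(v)
                    for c in v.children:
                        p.add(c)
            col = {lab: syms[int(rng.integers(len(syms)))] for lab in labs}
            assert tt.fitch_length(t, col) == brute_force_column_min(t, col)


class TestTsLength:
    def test_all_accommodated_equals_n(self, toys):
        true8, clean8, og_seq = toys["clean_eight"]
        ts = tt.encode_matrix(clean8, og_seq)
        length, violations = tt.ts_length(true8, ts)
        assert violations == 0
        assert length == ts.n_statements

    def test_star_tree_violates_everything(self, toys):
        _, clean8, og_seq = toys["clean_eight"]
        ts = tt.encode_matrix(clean8, og_seq)
        star = tt.parse_tree("(a,b,c,d,e,f,g,h," + ts.outgroup_label + ");")
        length, violations = tt.ts_length(star, ts)
        assert violations == ts.n_statements
        assert length == 2 * ts.n_statements

    def test_unrooted_without_outgroup_rejected(self, toys):
        _, clean8, og_seq = toys["clean_eight"]
        ts = tt.encode_matrix(clean8, og_seq)
        t = tt.parse_tree("(a,b,c,d,e,f,g,h);")
        with pytest.raises(ValueError):
            tt.ts_length(t, ts)

    def test_equals_fitch_over_expanded_columns(self, rng):
        """The MRCA accommodation rule reproduces summed Fitch lengths of
        the expanded binary columns — the module's central identity."""
        for _ in range(30):
            n = int(rng.integers(5, 10))
            labs = [f"t{i}" for i in range(n)]
            ncols = int(rng.integers(2, 15))
            aln = random_alignment(labs, ncols, rng, symbols="ACGT?-")
            og = "".join(np.array(list("ACGT"))[rng.integers(0, 4, ncols)])
            ts = tt.encode_matrix(aln, og)
            if ts.n_statements == 0:
                continue
            tree = random_tree(labs + [ts.outgroup_label], rng)
            length, _ = tt.ts_length(tree, ts)
            expanded = 0
            for (i, j, k) in ts.expanded_columns():
                col = {lab: "?" for lab in labs + [ts.outgroup_label]}
                col[labs[i]] = col[labs[j]] = "1"
                col[labs[k]] = col[ts.outgroup_label] = "0"
                expanded += tt.fitch_length(tree, col)
            assert length == expanded


class TestEnsembleStats:
    def test_min_max_steps_closed_forms(self):
        aln = Alignment(["a", "b", "c", "d", "e"], np.array([list(s) for s in "AACCG"]).reshape(5, 1))
        t = tt.parse_tree("((a,b),(c,(d,e)));")
        stats = char_stats(aln, t)
        assert stats.min_steps[0] == 2  # three observed states
        assert stats.max_steps[0] == 3  # 5 scored - largest class (2)

    def test_uninformative_character_leaves_ri_balance(self, rng):
        aln = random_alignment(["a", "b", "c", "d", "e"], 30, rng)
        t = random_tree(aln.taxa, rng)
        base = char_stats(aln, t)
        ci0, ri0 = ensemble_ci_ri(base)
        # append an autapomorphic column: m = g = 1, s = 1
        col = np.array([list("CAAAA")]).reshape(5, 1)
        aln2 = Alignment(aln.taxa, np.hstack([aln.data, col]))
        ci1, ri1 = ensemble_ci_ri(char_stats(aln2, t))
        assert ri1 == pytest.approx(ri0)
        assert ci1 != pytest.approx(ci0)  # CI does move

    def test_all_constant_ri_undefined(self):
        aln = Alignment(["a", "b", "c", "d"], np.array([list("AA")] * 4))
        t = tt.parse_tree("((a,b),(c,d));")
        ci, ri = ensemble_ci_ri(char_stats(aln, t))
        assert np.isnan(ri)

    def test_3ts_closed_form(self):
        ci, ri = tt.ensemble_stats_3ts(1208, 1279)
        assert round(ri, 4) == 0.9412


class TestSearch:
    def test_mp_matches_exact_on_small_dna(self, rng):
        for trial in range(5):
            aln = random_alignment([f"t{i}" for i in range(7)], 15, rng)
            ex = tt.exact_search(aln)
            mp = tt.mp_search(aln, n_addition_replicates=3, seed=trial)
            assert mp.length == ex.length

    def test_noiseless_data_recovers_generating_tree(self, toys):
        true8, clean8, og_seq = toys["clean_eight"]
        ts = tt.encode_matrix(clean8, og_seq)
        res = tt.mp_search(ts, n_addition_replicates=3, seed=0)
        assert res.length == ts.n_statements  # zero homoplasy
        best_keys = {
            t.root_with_outgroup(ts.outgroup_label).topology_key()
            for t in res.best_trees
        }
        truth = true8.copy()
        assert any(truth.clusters() <= key for key in best_keys)

    def test_same_seed_identical_result(self, rng):
        aln = random_alignment([f"t{i}" for i in range(8)], 25, rng)
        r1 = tt.mp_search(aln, n_addition_replicates=2, seed=99)
        r2 = tt.mp_search(aln, n_addition_replicates=2, seed=99)
        assert r1.length == r2.length
        assert [t.canonical_newick() for t in r1.best_trees] == [
            t.canonical_newick() for t in r2.best_trees
        ]

    def test_swap_radius_monotone(self, rng):
        aln = random_alignment([f"t{i}" for i in range(9)], 12, rng)
        lengths = {
            swap: tt.mp_search(aln, n_addition_replicates=1, seed=5, swap=swap).length
            for swap in ("nni", "spr", "tbr")
        }
        assert lengths["nni"] >= lengths["spr"] >= lengths["tbr"]

    def test_param_validation(self, rng):
        aln = random_alignment([f"t{i}" for i in range(5)], 5, rng)
        with pytest.raises(ValueError):
            tt.mp_search(aln, n_addition_replicates=0)
        with pytest.raises(ValueError):
            tt.mp_search(aln, swap="zigzag")

    def test_exact_search_constant_matrix_all_tie(self):
        aln = Alignment(["a", "b", "c", "d", "e"], np.array([list("AC")] * 5))
        res = tt.exact_search(aln)
        assert res.length == 0
        assert len(res.best_trees) == 15  # every 5-leaf topology

    def test_exact_search_quartet_signal(self):
        aln = Alignment(
            ["a", "b", "c", "d"],
            np.array([list("C"), list("C"), list("A"), list("A")]),
        )
        res = tt.exact_search(aln)
        assert res.length == 1
        assert frozenset("ab") in res.best_tree.splits() or frozenset("cd") in res.best_tree.splits()

    def test_exact_search_refuses_large(self, rng):
        aln = random_alignment([f"t{i}" for i in range(12)], 5, rng)
        with pytest.raises(ValueError, match="mp_search"):
            tt.exact_search(aln)


class TestJackknife:
    def test_zero_deletion_matches_full_search(self, rng):
        aln = random_alignment([f"t{i}" for i in range(6)], 40, rng)
        full = tt.mp_search(aln, n_addition_replicates=2, seed=0)
        from threetaxon.treecompare import strict_consensus

        cons = strict_consensus(full.best_trees)
        support = tt.jackknife(aln, reps=5, delete_fraction=0.0, seed=1)
        for split in cons.splits():
            assert support.get(split, 0) == 100.0

    def test_strong_signal_full_support(self, toys):
        _, clean8, og_seq = toys["clean_eight"]
        # replicate the diagnostic columns so deletion cannot erase signal
        boosted = Alignment(clean8.taxa, np.hstack([clean8.data] * 12))
        support = tt.jackknife(boosted, reps=8, delete_fraction=0.37, seed=3)
        # split {a,b}|rest is stored by the side not containing leaf 'a'
        assert support.get(frozenset("cdefgh"), 0) == 100.0
        assert support.get(frozenset("cd"), 0) == 100.0

    def test_fixed_seed_reproducible(self, rng):
        aln = random_alignment([f"t{i}" for i in range(6)], 30, rng)
        s1 = tt.jackknife(aln, reps=6, delete_fraction=0.37, seed=7)
        s2 = tt.jackknife(aln, reps=6, delete_fraction=0.37, seed=7)
        assert s1 == s2

    def test_fraction_validated(self, rng):
        aln = random_alignment([f"t{i}" for i in range(5)], 10, rng)
        with pytest.raises(ValueError):
            tt.jackknife(aln, reps=2, delete_fraction=1.5)
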