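import numpy as np
import pytest

import patevol as pv
from patevol.parsimony import MprCapExceeded, enumerate_mprs, hartigan_sets, sankoff

from conftest import brute_force_mprs, fitch_length, random_matrix, random_tree
from patevol.tree import Node, Tree


def cherry(a="0", b="2"):
    root = Node()
    root.add_child(Node("A", branch_length=1.0))
    root.add_child(Node("B", branch_length=1.0))
    tree = Tree(root)
    matrix = pv.CharacterMatrix.from_symbols({"A": a, "B": b})
    return tree, matrix


UNORDERED = pv.make_step_matrix("unordered", 3)
ORDERED = pv.make_step_matrix("ordered", 3)


class TestSankoff:
    def test_constant_character_costs_nothing(self, rng):
        tree = random_tree(rng, 8)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "2" for t in tree.tip_labels()})
        res = sankoff(tree, matrix, UNORDERED)
        assert res.total == 0
        assert res.root_states() == frozenset({2})

    def test_cherry_cost_depends_on_ordering_scheme(self):
        tree, matrix = cherry("0", "2")
        assert sankoff(tree, matrix, UNORDERED).total == 1
        assert sankoff(tree, matrix, ORDERED).total == 2

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            sankoff(Tree(Node()), pv.CharacterMatrix({}, k=3), UNORDERED)

    @pytest.mark.parametrize("steps", [UNORDERED, ORDERED],
                             ids=["unordered", "ordered"])
    def test_total_matches_exhaustive_minimum(self, rng, steps):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(4, 7)))
            matrix = random_matrix(rng, tree)
            res = sankoff(tree, matrix, steps)
            best, _ = brute_force_mprs(tree, matrix, steps)
            assert res.total == pytest.approx(best)

    def test_total_invariant_under_child_reordering(self, rng):
        tree = random_tree(rng, 9)
        matrix = random_matrix(rng, tree)
        before = sankoff(tree, matrix, ORDERED).total
        for node in tree.preorder():
            node.children.reverse()
        assert sankoff(tree, matrix, ORDERED).total == before

    def test_ordered_never_cheaper_than_unordered(self, rng):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            matrix = random_matrix(rng, tree)
            assert sankoff(tree, matrix, ORDERED).total >= \
                sankoff(tree, matrix, UNORDERED).total

    def test_unordered_equals_fitch_hartigan_length(self, rng):
        for _ in range(1000):
            tree = random_tree(rng, int(rng.integers(2, 10)))
            matrix = random_matrix(rng, tree)
            assert sankoff(tree, matrix, UNORDERED).total == \
                fitch_length(tree, matrix)


class TestStateSets:
    def test_cherry_root_symmetric_tie(self):
        tree, matrix = cherry("0", "2")
        sets = hartigan_sets(tree, matrix)
        assert sets[tree.root] == frozenset({0, 2})

    def test_sets_equal_states_realized_across_all_mprs(self, rng):
        for _ in range(200):
            tree = random_tree(rng, int(rng.integers(4, 7)))
            matrix = random_matrix(rng, tree)
            _, assigns = brute_force_mprs(tree, matrix, UNORDERED)
            realized = {n: frozenset(a[n] for a in assigns)
                        for n in tree.preorder()}
            assert hartigan_sets(tree, matrix) == realized

    def test_step_matrix_sets_also_match_enumeration(self, rng):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(4, 7)))
            matrix = random_matrix(rng, tree)
            res = sankoff(tree, matrix, ORDERED)
            _, assigns = brute_force_mprs(tree, matrix, ORDERED)
            realized = {n: frozenset(a[n] for a in assigns)
                        for n in tree.preorder()}
            assert res.state_sets == realized


class TestEnumeration:
    def test_unambiguous_data_single_mpr(self, rng):
        tree = random_tree(rng, 6)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "1" for t in tree.tip_labels()})
        mprs = enumerate_mprs(sankoff(tree, matrix, UNORDERED))
        assert len(mprs) == 1

    def test_cherry_has_exactly_two_mprs(self):
        tree, matrix = cherry("0", "2")
        mprs = enumerate_mprs(sankoff(tree, matrix, UNORDERED))
        assert len(mprs) == 2
        assert sorted(m[tree.root] for m in mprs) == [0, 2]

    def test_count_matches_exhaustive_count(self, rng):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(5, 8)))
            matrix = random_matrix(rng, tree)
            res = sankoff(tree, matrix, UNORDERED)
            _, assigns = brute_force_mprs(tree, matrix, UNORDERED)
            assert len(enumerate_mprs(res, cap=200000)) == len(assigns)

    def test_every_mpr_cost_sum_matches_total(self, rng):
        for _ in range(50):
            tree = random_tree(rng, int(rng.integers(4, 8)))
            matrix = random_matrix(rng, tree)
            for steps in (UNORDERED, ORDERED):
                res = sankoff(tree, matrix, steps)
                for m in enumerate_mprs(res, cap=100000):
                    cost = sum(steps(m[n.parent], m[n])
                               for n in tree.preorder() if n.parent)
                    assert cost == pytest.approx(res.total)

    def test_cap_exceeded_is_distinguished(self):
        tree, matrix = cherry("0", "2")
        res = sankoff(tree, matrix, UNORDERED)
        with pytest.raises(MprCapExceeded):
            enumerate_mprs(res, cap=1)
        assert len(enumerate_mprs(res, cap=2)) == 2

    def test_deterministic_order(self, rng):
        tree = random_tree(rng, 7)
        matrix = random_matrix(rng, tree, missing_prob=0.4)
        res = sankoff(tree, matrix, UNORDERED)
        a = enumerate_mprs(res)
        b = enumerate_mprs(sankoff(tree, matrix, UNORDERED))
        post = list(tree.postorder())
        assert [[m[n] for n in post] for m in a] == [[m[n] for n in post] for m in b]
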