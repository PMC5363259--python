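import numpy as np
import pytest

import patevol as pv
from patevol.origins import (GAIN, LOSS, count_transitions, ml_transition_bracket,
                             min_max_gains_over_mprs,
                             min_max_transitions_over_mprs, scenario_sweep,
                             sweep_table)
from patevol.parsimony import enumerate_mprs, sankoff
from patevol.tree import Clade, Node, Tree

from conftest import brute_force_mprs, random_matrix, random_tree

UNORDERED = pv.make_step_matrix("unordered", 3)
ORDERED = pv.make_step_matrix("ordered", 3)


def chain(states):
    """root -> a -> tip chain with the given assigned states."""
    root = Node("r")
    a = root.add_child(Node("a", branch_length=1.0))
    tip = a.add_child(Node("tip", branch_length=1.0))
    tree = Tree(root)
    assignment = dict(zip([root, a, tip], states))
    return tree, assignment


class TestCountTransitions:
    def test_no_gains_in_constant_history(self):
        tree, assignment = chain([0, 0, 0])
        assert count_transitions(tree, assignment) == 0

    def test_single_gain_edge_scan(self):
        tree, assignment = chain([0, 2, 2])
        assert count_transitions(tree, assignment) == 1
        assert count_transitions(tree, assignment, *LOSS) == 0

    def test_regain_counts_as_origin(self):
        tree, assignment = chain([2, 1, 2])
        assert count_transitions(tree, assignment) == 1  # the 1 -> 2 edge
        assert count_transitions(tree, assignment, *LOSS) == 1

    def test_incomplete_assignment_rejected(self):
        tree, assignment = chain([0, 2, 2])
        assignment.pop(tree.find("a"))
        with pytest.raises(ValueError):
            count_transitions(tree, assignment)

    def test_clade_restriction_and_stem_edge(self):
        # root(0) -> [X(2) -> (t1(2), t2(2))], out(0)
        root = Node("r")
        x = root.add_child(Node("X", branch_length=1.0))
        t1 = x.add_child(Node("t1", branch_length=1.0))
        t2 = x.add_child(Node("t2", branch_length=1.0))
        out = root.add_child(Node("out", branch_length=1.0))
        tree = Tree(root)
        assignment = {root: 0, x: 2, t1: 2, t2: 2, out: 0}
        clade = Clade("inner", ["t1", "t2"])
        assert count_transitions(tree, assignment, clade=clade) == 1
        assert count_transitions(tree, assignment, clade=clade,
                                 include_stem=False) == 0


class TestMinMaxOverMprs:
    def test_unambiguous_instance_min_equals_max(self, rng):
        tree = random_tree(rng, 6)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "2" for t in tree.tip_labels()})
        assert min_max_gains_over_mprs(tree, matrix, UNORDERED) == (0, 0)

    def test_cherry_bracket_is_zero_to_one(self):
        root = Node()
        root.add_child(Node("A", branch_length=1.0))
        root.add_child(Node("B", branch_length=1.0))
        tree = Tree(root)
        matrix = pv.CharacterMatrix.from_symbols({"A": "0", "B": "2"})
        assert min_max_gains_over_mprs(tree, matrix, UNORDERED) == (0, 1)

    @pytest.mark.parametrize("steps", [UNORDERED, ORDERED],
                             ids=["unordered", "ordered"])
    @pytest.mark.parametrize("kind", [GAIN, LOSS], ids=["gains", "losses"])
    def test_dp_equals_full_enumeration(self, rng, steps, kind):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(4, 8)))
            matrix = random_matrix(rng, tree)
            _, assigns = brute_force_mprs(tree, matrix, steps)
            counts = [count_transitions(tree, a, *kind) for a in assigns]
            dp = min_max_transitions_over_mprs(tree, matrix, steps, *kind)
            assert dp == (min(counts), max(counts))

    def test_dp_equals_enumeration_with_clade_restriction(self, rng):
        for _ in range(30):
            tree = random_tree(rng, 6)
            matrix = random_matrix(rng, tree)
            labels = tree.tip_labels()
            clade = Clade("c", labels[:3])
            _, assigns = brute_force_mprs(tree, matrix, UNORDERED)
            counts = [count_transitions(tree, a, *GAIN, clade=clade)
                      for a in assigns]
            dp = min_max_transitions_over_mprs(tree, matrix, UNORDERED,
                                               *GAIN, clade=clade)
            assert dp == (min(counts), max(counts))

    def test_recoding_evidence_to_missing_cannot_raise_minimum_at_equal_cost(self, rng):
        # weakening a 2-coded tip to "?" keeps every original MPR valid at
        # unchanged cost, so whenever the optimal score is unchanged the
        # minimum gain count cannot rise (if the score drops, the set of
        # MPRs is replaced wholesale and no monotonicity holds)
        for _ in range(50):
            tree = random_tree(rng, 7)
            matrix = random_matrix(rng, tree, missing_prob=0.0)
            two_coded = [t for t in matrix.taxa() if matrix[t] == frozenset({2})]
            if not two_coded:
                continue
            before = sankoff(tree, matrix, UNORDERED)
            lo, _ = min_max_gains_over_mprs(tree, matrix, UNORDERED)
            weaker = matrix.with_taxon(two_coded[0], frozenset({0, 1, 2}))
            after = sankoff(tree, weaker, UNORDERED)
            lo2, _ = min_max_gains_over_mprs(tree, weaker, UNORDERED)
            assert after.total <= before.total
            if after.total == before.total:
                assert lo2 <= lo

    def test_binary_collapsed_data_same_bracket_under_both_schemes(self, rng):
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(3, 8)))
            matrix = pv.CharacterMatrix.from_symbols(
                {t: str(rng.choice(["0", "2"])) for t in tree.tip_labels()})
            assert min_max_gains_over_mprs(tree, matrix, UNORDERED) == \
                min_max_gains_over_mprs(tree, matrix, ORDERED)

    def test_gain_loss_balance_reconstructs_tip_state(self, rng):
        # along any root-to-tip path of an MPR, the tip is ossified iff
        # gains exceed losses when states are collapsed to {non-2, 2}
        for _ in range(20):
            tree = random_tree(rng, 6)
            matrix = random_matrix(rng, tree)
            res = sankoff(tree, matrix, UNORDERED)
            for m in enumerate_mprs(res, cap=50000):
                for tip in tree.tips():
                    path, node = [], tip
                    while node is not None:
                        path.append(node)
                        node = node.parent
                    path = path[::-1]
                    g = sum(1 for p, c in zip(path, path[1:])
                            if m[p] != 2 and m[c] == 2)
                    l = sum(1 for p, c in zip(path, path[1:])
                            if m[p] == 2 and m[c] != 2)
                    root_is_2 = m[tree.root] == 2
                    assert (m[tip] == 2) == (g > l if not root_is_2 else g >= l)


class TestMlBracket:
    def test_forced_and_possible_edges(self):
        root = Node("r")
        a = root.add_child(Node("a", branch_length=1.0))
        b = a.add_child(Node("b", branch_length=1.0))
        tree = Tree(root)
        mapped = {root: frozenset({0}), a: frozenset({0, 1}),
                  b: frozenset({2})}
        lo, hi = ml_transition_bracket(tree, mapped)
        assert (lo, hi) == (1, 1)  # a -> b forced; root -> a never a gain
        mapped[a] = frozenset({0, 2})
        lo, hi = ml_transition_bracket(tree, mapped)
        assert (lo, hi) == (0, 2)  # both edges possible, neither forced


class TestScenarioSweep:
    def test_single_variant_single_scheme_single_row(self):
        fx = pv.load_fixture("metatheria_fig6")
        rows = scenario_sweep(fx.tree, fx.matrix, {"main": fx.variants["main"]},
                              fx.clades, schemes=("unordered",))
        assert len(rows) == 1
        assert rows[0].scheme == "unordered"
        assert set(rows[0].per_clade) == set(fx.clades)

    def test_row_cardinality_and_order_deterministic(self):
        fx = pv.load_fixture("mammaliaformes_fig5")
        rows = scenario_sweep(fx.tree, fx.matrix, fx.variants, fx.clades)
        assert len(rows) == len(fx.variants) * 2
        tags = [(r.variant, r.scheme) for r in rows]
        rows2 = scenario_sweep(fx.tree, fx.matrix, fx.variants, fx.clades)
        assert tags == [(r.variant, r.scheme) for r in rows2]
        table = sweep_table(rows)
        assert list(table["variant"]) == [t[0] for t in tags]
        assert "crown_mammalia.min_gains" in table.columns

    def test_ml_rows_appended_per_variant(self):
        fx = pv.load_fixture("metatheria_fig6")
        rows = scenario_sweep(fx.tree, fx.matrix,
                              {"main": fx.variants["main"]}, fx.clades,
                              schemes=("unordered",), ml=True)
        assert [r.scheme for r in rows] == ["unordered", "ml"]
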