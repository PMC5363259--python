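import math

import numpy as np
import pytest
from scipy.linalg import expm

import patevol as pv
from patevol.mk import (MkModel, OrderedRatesModel, fit_rate, map_states,
                        marginal_probs, mk_loglik, transition_matrix)

from conftest import (brute_force_loglik, brute_force_marginals, random_matrix,
                      random_tree)
from patevol.tree import Node, Tree


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(MkModel(q=0.02), 0.0)
        assert np.allclose(P, np.eye(3))

    def test_long_time_reaches_stationarity(self):
        P = transition_matrix(MkModel(q=0.1), 1e6)
        assert np.allclose(P, np.full((3, 3), 1 / 3))

    def test_rows_sum_to_one(self):
        P = transition_matrix(MkModel(q=0.01), 37.5)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_matches_numerical_matrix_exponential(self):
        model = MkModel(q=0.01)
        P = transition_matrix(model, 50.0)
        assert np.allclose(P, expm(model.generator * 50.0), atol=1e-10)

    def test_random_q_t_match_expm(self, rng):
        for _ in range(50):
            model = MkModel(q=float(rng.uniform(1e-4, 0.5)))
            t = float(rng.uniform(0, 300))
            assert np.allclose(transition_matrix(model, t),
                               expm(model.generator * t), atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkModel(q=0.01), -1.0)

    def test_ordered_rates_generator_blocks_direct_jumps(self):
        m = OrderedRatesModel(g01=0.1, g12=0.2, l10=0.05, l21=0.02)
        Q = m.generator
        assert Q[0, 2] == 0 and Q[2, 0] == 0
        assert np.allclose(Q.sum(axis=1), 0.0)


class TestLoglik:
    def test_frozen_chain_constant_data_likelihood_is_prior_mass(self, rng):
        tree = random_tree(rng, 5)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "2" for t in tree.tip_labels()})
        ll = mk_loglik(tree, matrix, MkModel(q=0.0))
        assert ll == pytest.approx(math.log(1 / 3))

    def test_frozen_chain_conflicting_data_is_minus_infinity(self):
        root = Node()
        root.add_child(Node("A", branch_length=1.0))
        root.add_child(Node("B", branch_length=1.0))
        matrix = pv.CharacterMatrix.from_symbols({"A": "0", "B": "2"})
        assert mk_loglik(Tree(root), matrix, MkModel(q=0.0)) == -math.inf

    def test_pruning_matches_exhaustive_sum(self, rng):
        for _ in range(100):
            tree = random_tree(rng, 4)
            matrix = random_matrix(rng, tree)
            model = MkModel(q=float(rng.uniform(1e-3, 0.1)))
            assert mk_loglik(tree, matrix, model) == pytest.approx(
                brute_force_loglik(tree, matrix, model), abs=1e-10)

    def test_invariant_to_child_ordering(self, rng):
        tree = random_tree(rng, 8)
        matrix = random_matrix(rng, tree)
        model = MkModel(q=0.02)
        before = mk_loglik(tree, matrix, model)
        for node in tree.preorder():
            node.children.reverse()
        assert mk_loglik(tree, matrix, model) == pytest.approx(before)

    def test_rescaling_keeps_deep_trees_finite(self):
        tree = pv.yule_tree(300, birth_rate=0.05, seed=5)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "012"[i % 3] for i, t in enumerate(tree.tip_labels())})
        ll = mk_loglik(tree, matrix, MkModel(q=0.002))
        assert math.isfinite(ll)

    def test_ordered_rates_model_agrees_with_enumeration(self, rng):
        for _ in range(20):
            tree = random_tree(rng, 4)
            matrix = random_matrix(rng, tree)
            model = OrderedRatesModel(g01=0.02, g12=0.05, l10=0.01, l21=0.03)
            assert mk_loglik(tree, matrix, model) == pytest.approx(
                brute_force_loglik(tree, matrix, model), abs=1e-10)


class TestFitRate:
    def test_constant_data_lands_on_lower_bound_with_flag(self, rng):
        tree = random_tree(rng, 10)
        matrix = pv.CharacterMatrix.from_symbols(
            {t: "2" for t in tree.tip_labels()})
        fit = fit_rate(tree, matrix)
        assert fit.at_bound
        assert fit.model.q == pytest.approx(fit.bounds[0])

    def test_profile_optimality(self, rng):
        tree = pv.yule_tree(60, birth_rate=0.05, seed=11)
        sim = pv.simulate_trait(tree, pv.SimConfig(model=MkModel(q=0.01),
                                                   root_state=0, seed=3))
        matrix = pv.CharacterMatrix.from_symbols(sim.tip_symbols())
        fit = fit_rate(tree, matrix)
        assert not fit.at_bound
        for factor in (1.1, 1 / 1.1):
            assert fit.loglik >= mk_loglik(
                tree, matrix, MkModel(q=fit.model.q * factor)) - 1e-9


class TestMarginals:
    def test_observed_tip_marginal_is_certain(self, rng):
        tree = random_tree(rng, 4)
        matrix = random_matrix(rng, tree, missing_prob=0.0)
        recon = marginal_probs(tree, matrix, MkModel(q=0.01))
        for tip in tree.tips():
            state = next(iter(matrix[tip.label]))
            assert recon[tip][state] == pytest.approx(1.0)

    def test_vectors_normalised(self, rng):
        tree = random_tree(rng, 9)
        matrix = random_matrix(rng, tree)
        recon = marginal_probs(tree, matrix, MkModel(q=0.02))
        for node in tree.preorder():
            assert recon[node].sum() == pytest.approx(1.0, abs=1e-9)

    def test_match_exhaustive_posteriors(self, rng):
        for _ in range(50):
            tree = random_tree(rng, 4)
            matrix = random_matrix(rng, tree)
            model = MkModel(q=float(rng.uniform(1e-3, 0.1)))
            recon = marginal_probs(tree, matrix, model)
            brute = brute_force_marginals(tree, matrix, model)
            for node in tree.preorder():
                assert np.allclose(recon[node], brute[node], atol=1e-10)

    def test_saturation_limit_gives_uniform_marginals(self, rng):
        tree = random_tree(rng, 6)
        matrix = random_matrix(rng, tree, missing_prob=0.0)
        recon = marginal_probs(tree, matrix, MkModel(q=100.0))
        for node in tree.preorder():
            if not node.is_tip:
                assert np.allclose(recon[node], 1 / 3, atol=1e-6)

    def test_slow_limit_recovers_parsimony_on_conflict_free_data(self, rng):
        # one clade fixed 2, the rest fixed 0: as q -> 0 the marginal map
        # must agree with the (unique) parsimony reconstruction
        tree = pv.yule_tree(12, birth_rate=0.05, seed=2)
        anchor = tree.mrca(tree.tip_labels()[:3])
        inside = {n.label for n in pv.Tree(anchor).tips()}
        matrix = pv.CharacterMatrix.from_symbols(
            {t: ("2" if t in inside else "0") for t in tree.tip_labels()})
        recon = marginal_probs(tree, matrix, MkModel(q=1e-7))
        mapped = map_states(recon, threshold=0.05)
        sets = pv.hartigan_sets(tree, matrix)
        unique = {n: next(iter(s)) for n, s in sets.items() if len(s) == 1}
        for node, state in unique.items():
            assert mapped[node] == frozenset({state})


class TestMapStates:
    def test_clear_winner(self):
        recon = _fake_recon([(0.1, 0.2, 0.7)])
        assert list(map_states(recon).values())[0] == frozenset({2})

    def test_near_tie_reported_as_ambiguous(self):
        recon = _fake_recon([(0.49, 0.51, 0.0)])
        assert list(map_states(recon, threshold=0.05).values())[0] \
            == frozenset({0, 1})


def _fake_recon(vectors):
    nodes = {Node(f"n{i}"): np.array(v) for i, v in enumerate(vectors)}
    tree = Tree(next(iter(nodes)))
    return pv.MarginalReconstruction(tree=tree, model=MkModel(q=0.01),
                                     node_probs=nodes, loglik=0.0)
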