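"""Shared generators and independent brute-force oracles.

The oracles deliberately avoid the library's dynamic programmes: costs,
MPR sets and likelihoods are recomputed by exhaustive enumeration over
all joint state assignments, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import patevol as pv
from patevol.tree import Node, Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20170321)


def random_tree(rng, n_tips: int, polytomy_prob: float = 0.3,
                max_len: float = 5.0) -> Tree:
    """Random rooted tree (with occasional polytomies) on labelled tips."""
    nodes = [Node(f"t{i + 1}", branch_length=float(rng.uniform(0.1, max_len)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) > 2 and rng.random() < polytomy_prob) else 2
        idx = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        parent = Node(branch_length=float(rng.uniform(0.1, max_len)))
        for i in idx:
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    nodes[0].branch_length = None
    return Tree(nodes[0])


def random_matrix(rng, tree: Tree, missing_prob: float = 0.1
                  ) -> pv.CharacterMatrix:
    p = (1 - missing_prob) / 3
    syms = {lab: str(rng.choice(["0", "1", "2", "?"],
                                p=[p, p, p, missing_prob]))
            for lab in tree.tip_labels()}
    return pv.CharacterMatrix.from_symbols(syms)


def brute_force_mprs(tree: Tree, matrix: pv.CharacterMatrix,
                     steps: pv.StepMatrix) -> tuple[float, list[dict]]:
    """Minimal cost and every minimal assignment, by full enumeration."""
    nodes = list(tree.preorder())
    mat, _ = pv.validate_matrix(matrix, tree)
    choices = [sorted(mat[n.label]) if n.is_tip else list(range(steps.k))
               for n in nodes]
    best, assigns = math.inf, []
    for combo in itertools.product(*choices):
        amap = dict(zip(nodes, combo))
        c = sum(steps(amap[n.parent], amap[n]) for n in nodes if n.parent)
        if c < best - 1e-9:
            best, assigns = c, [dict(amap)]
        elif abs(c - best) <= 1e-9:
            assigns.append(dict(amap))
    return best, assigns


def brute_force_loglik(tree: Tree, matrix: pv.CharacterMatrix, model) -> float:
    """Likelihood by summing over every joint ancestral+tip assignment."""
    nodes = list(tree.preorder())
    mat, _ = pv.validate_matrix(matrix, tree)
    P = {n: model.transition(n.branch_length) for n in nodes if n.parent}
    choices = [sorted(mat[n.label]) if n.is_tip else list(range(model.k))
               for n in nodes]
    total = 0.0
    for combo in itertools.product(*choices):
        amap = dict(zip(nodes, combo))
        p = model.prior[amap[tree.root]]
        for n in nodes:
            if n.parent:
                p *= P[n][amap[n.parent], amap[n]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_force_marginals(tree: Tree, matrix: pv.CharacterMatrix, model
                          ) -> dict:
    nodes = list(tree.preorder())
    mat, _ = pv.validate_matrix(matrix, tree)
    P = {n: model.transition(n.branch_length) for n in nodes if n.parent}
    choices = [sorted(mat[n.label]) if n.is_tip else list(range(model.k))
               for n in nodes]
    post = {n: np.zeros(model.k) for n in nodes}
    for combo in itertools.product(*choices):
        amap = dict(zip(nodes, combo))
        p = model.prior[amap[tree.root]]
        for n in nodes:
            if n.parent:
                p *= P[n][amap[n.parent], amap[n]]
        for n in nodes:
            post[n][amap[n]] += p
    return {n: v / v.sum() for n, v in post.items()}


def fitch_length(tree: Tree, matrix: pv.CharacterMatrix) -> int:
    """Independent Fitch/Hartigan parsimony length (uniform costs),
    computed by the classic intersection/union count generalized to
    polytomies via state-count maximisation."""
    mat, _ = pv.validate_matrix(matrix, tree)
    length = 0
    sets: dict[Node, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[node] = mat[node.label]
            continue
        counts = {s: sum(1 for c in node.children if s in sets[c])
                  for s in range(matrix.k)}
        top = max(counts.values())
        sets[node] = frozenset(s for s, c in counts.items() if c == top)
        length += len(node.children) - top
    return length
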