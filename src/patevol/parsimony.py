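"""Multistate parsimony ancestral reconstruction on rooted trees.

Implements generalized (Sankoff) parsimony with an arbitrary step matrix,
the per-node sets of states realizable in at least one most-parsimonious
reconstruction (MPR), and exhaustive MPR enumeration.  All routines
handle polytomies natively and treat ``?`` tips as freely assignable
(cost zero in every state), the standard missing-data convention.

The root is treated as in plain unweighted parsimony: the total score is
the minimum over root states, with no stationary weighting.

Dynamic programme
-----------------
Inside (up) pass, tips to root::

    cost_v(i) = sum over children c of min_j [ step(i, j) + cost_c(j) ]

with tip vectors 0 at observed states and +inf elsewhere.  Outside (down)
pass, root to tips::

    out_c(j) = min_i [ out_v(i) + cost_v(i) - S(c | i) + step(i, j) ]

where ``S(c | i) = min_j step(i,j) + cost_c(j)`` is child c's
contribution to ``cost_v(i)``.  State ``i`` occurs at node ``v`` in some
MPR iff ``cost_v(i) + out_v(i)`` equals the total minimum — for uniform
costs this reproduces Hartigan's up/down construction, and it extends it
to step matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characters import CharacterMatrix, StepMatrix, make_step_matrix, validate_matrix
from .tree import Node, Tree

__all__ = [
    "SankoffResult", "MprAssignment", "MprCapExceeded",
    "sankoff", "hartigan_sets", "mpr_state_sets", "enumerate_mprs",
]

INF = np.inf
_TOL = 1e-9


class MprCapExceeded(RuntimeError):
    """More MPRs exist than the enumeration cap allows."""

    def __init__(self, cap: int):
        super().__init__(f"number of MPRs exceeds cap {cap}; enumeration truncated")
        self.cap = cap


@dataclass
class MprAssignment:
    """One full most-parsimonious assignment of states to all nodes."""

    states: dict[Node, int]
    cost: float

    def __getitem__(self, node: Node) -> int:
        return self.states[node]


@dataclass
class SankoffResult:
    """Cost vectors, optimal score and per-node MPR state sets."""

    tree: Tree
    steps: StepMatrix
    matrix: CharacterMatrix
    cost: dict[Node, np.ndarray]
    outside: dict[Node, np.ndarray]
    total: float
    state_sets: dict[Node, frozenset[int]] = field(repr=False, default_factory=dict)

    @property
    def k(self) -> int:
        return self.steps.k

    def root_states(self) -> frozenset[int]:
        return self.state_sets[self.tree.root]


def _tip_vector(states: frozenset[int], k: int) -> np.ndarray:
    vec = np.full(k, INF)
    vec[sorted(states)] = 0.0
    return vec


def sankoff(tree: Tree, matrix: CharacterMatrix, steps: StepMatrix) -> SankoffResult:
    """Generalized parsimony DP over ``tree`` for one character.

    Tips absent from ``matrix`` are coded ``?``.  Raises ``ValueError``
    on an empty tree.
    """
    if tree.root is None or not any(t.label for t in tree.tips()):
        raise ValueError("empty tree")
    matrix, _ = validate_matrix(matrix, tree)
    k = steps.k
    S = steps.costs  # (k, k): S[i, j] = cost of parent i -> child j

    cost: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            cost[node] = _tip_vector(matrix[node.label], k)
        else:
            vec = np.zeros(k)
            for child in node.children:
                # child contribution for every parent state at once
                vec += np.min(S + cost[child][None, :], axis=1)
            cost[node] = vec

    total = float(np.min(cost[tree.root]))

    outside: dict[Node, np.ndarray] = {tree.root: np.zeros(k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        base = outside[node] + cost[node]  # total above+at node, per state
        for child in node.children:
            contrib = np.min(S + cost[child][None, :], axis=1)  # S(child | i)
            # out_child(j) = min_i [ base(i) - contrib(i) + S[i, j] ]
            outside[child] = np.min((base - contrib)[:, None] + S, axis=0)

    state_sets: dict[Node, frozenset[int]] = {}
    for node in tree.preorder():
        tot = cost[node] + outside[node]
        state_sets[node] = frozenset(np.nonzero(tot <= total + _TOL)[0].tolist())

    return SankoffResult(tree=tree, steps=steps, matrix=matrix, cost=cost,
                         outside=outside, total=total, state_sets=state_sets)


def mpr_state_sets(tree: Tree, matrix: CharacterMatrix,
                   steps: StepMatrix) -> dict[Node, frozenset[int]]:
    """Per-node sets of states occurring in at least one MPR."""
    return sankoff(tree, matrix, steps).state_sets


def hartigan_sets(tree: Tree, matrix: CharacterMatrix) -> dict[Node, frozenset[int]]:
    """MPR state sets under uniform (unordered) costs.

    For uniform costs the inside/outside construction coincides with
    Hartigan's up/down passes generalized to polytomies.
    """
    return mpr_state_sets(tree, matrix, make_step_matrix("unordered", matrix.k))


def enumerate_mprs(result: SankoffResult, cap: int = 1_000_000) -> list[MprAssignment]:
    """All distinct minimal-cost assignments, in deterministic order.

    Assignments are returned sorted by their state tuple in postorder
    node order, states ascending.  If more than ``cap`` MPRs exist a
    :class:`MprCapExceeded` is raised, distinguishing a truncated
    enumeration from a complete one.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    tree, cost, S = result.tree, result.cost, result.steps.costs
    pre = list(tree.preorder())
    out: list[MprAssignment] = []
    assignment: dict[Node, int] = {}

    def rec(i: int) -> None:
        if i == len(pre):
            if len(out) >= cap:
                raise MprCapExceeded(cap)
            out.append(MprAssignment(states=dict(assignment), cost=result.total))
            return
        node = pre[i]
        if node.parent is None:
            vals = cost[node]
            best = result.total
        else:
            vals = S[assignment[node.parent], :] + cost[node]
            best = float(np.min(vals))
        for j in sorted(int(x) for x in np.nonzero(vals <= best + _TOL)[0]):
            assignment[node] = j
            rec(i + 1)
        assignment.pop(node, None)

    rec(0)
    post_nodes = list(tree.postorder())
    out.sort(key=lambda a: tuple(a.states[n] for n in post_nodes))
    return out
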