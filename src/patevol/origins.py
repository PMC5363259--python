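"""Counting independent origins and losses of the ossified patella.

An *origin* (gain) is an edge whose parent state is 0 or 1 and whose
child state is 2 — so re-acquisition of a bony patella after reduction
to a patelloid (1 -> 2, as in Tarsipedidae) counts as an origin.  A
*loss* is the reverse (parent 2, child 0 or 1).  Counts are taken over
all most-parsimonious reconstructions, giving a [min, max] bracket, or
over maximum-likelihood state maps, where ambiguous nodes contribute a
bracket instead of a point count.

Counts can be restricted to a clade; by default the clade's stem edge is
included, so an origin reconstructed "in the ancestor of Sparassodonta
and Marsupialia" registers inside Metatheria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import CharacterMatrix, StepMatrix
from .parsimony import MprAssignment, SankoffResult, sankoff
from .tree import Clade, Node, Tree

__all__ = [
    "GAIN", "LOSS", "TransitionSummary",
    "count_transitions", "min_max_transitions_over_mprs",
    "min_max_gains_over_mprs", "ml_transition_bracket", "scenario_sweep",
]

#: (from_states, to_states) for a gain of the ossified state.
GAIN = (frozenset({0, 1}), frozenset({2}))
#: (from_states, to_states) for a loss of the ossified state.
LOSS = (frozenset({2}), frozenset({0, 1}))

_TOL = 1e-9


def _counted_children(tree: Tree, clade: Clade | None, include_stem: bool,
                      exclude_tip_edges: frozenset[str] = frozenset()
                      ) -> set[Node] | None:
    """Child-nodes of counted edges; ``None`` means every non-root node.

    ``exclude_tip_edges`` removes the terminal edges of the named tips
    from the count (used e.g. to restrict a tally to stem lineages by
    leaving out collapsed crown-group terminals).
    """
    if clade is None and not exclude_tip_edges:
        return None
    if clade is None:
        anchor = tree.root
    else:
        anchor = tree.mrca(clade.members)
    counted: set[Node] = set()
    stack = list(anchor.children)
    while stack:
        n = stack.pop()
        counted.add(n)
        stack.extend(n.children)
    if clade is not None and include_stem and anchor.parent is not None:
        counted.add(anchor)
    if exclude_tip_edges:
        counted = {n for n in counted
                   if not (n.is_tip and n.label in exclude_tip_edges)}
    return counted


def count_transitions(tree: Tree, assignment: MprAssignment | dict[Node, int],
                      from_states: frozenset[int] = GAIN[0],
                      to_states: frozenset[int] = GAIN[1],
                      clade: Clade | None = None,
                      include_stem: bool = True) -> int:
    """Scan edges of one full assignment and count matching transitions."""
    states = assignment.states if isinstance(assignment, MprAssignment) else assignment
    counted = _counted_children(tree, clade, include_stem)
    n = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        if counted is not None and node not in counted:
            continue
        if node not in states or node.parent not in states:
            raise ValueError("assignment does not cover all counted nodes")
        if states[node.parent] in from_states and states[node] in to_states:
            n += 1
    return n


def min_max_transitions_over_mprs(
        tree: Tree, matrix: CharacterMatrix, steps: StepMatrix,
        from_states: frozenset[int] = GAIN[0],
        to_states: frozenset[int] = GAIN[1],
        clade: Clade | None = None,
        include_stem: bool = True,
        exclude_tip_edges: frozenset[str] = frozenset(),
        result: SankoffResult | None = None) -> tuple[int, int]:
    """Bracket of transition counts over *all* MPRs, by dynamic programme.

    Every globally optimal assignment chooses, for each edge given the
    parent state ``i``, a child state from ``argmin_j step(i,j) +
    cost_child(j)``; the programme therefore carries, per node and state,
    the min and max transition count achievable among optimal subtree
    assignments, which is exact and scales to large polytomous trees
    where full enumeration would explode.
    """
    if result is None:
        result = sankoff(tree, matrix, steps)
    S = result.steps.costs
    k = result.k
    counted = _counted_children(tree, clade, include_stem, exclude_tip_edges)
    frm = np.array([i in from_states for i in range(k)])
    to = np.array([j in to_states for j in range(k)])

    tmin: dict[Node, np.ndarray] = {}
    tmax: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            tmin[node] = np.zeros(k)
            tmax[node] = np.zeros(k)
            continue
        lo = np.zeros(k)
        hi = np.zeros(k)
        for child in node.children:
            vals = S + result.cost[child][None, :]   # (parent i, child j)
            best = vals.min(axis=1)
            opt = vals <= best[:, None] + _TOL
            ind = (frm[:, None] & to[None, :]).astype(float) \
                if (counted is None or child in counted) else np.zeros((k, k))
            cand_lo = np.where(opt, ind + tmin[child][None, :], np.inf)
            cand_hi = np.where(opt, ind + tmax[child][None, :], -np.inf)
            lo += cand_lo.min(axis=1)
            hi += cand_hi.max(axis=1)
        tmin[node] = lo
        tmax[node] = hi

    root = tree.root
    opt_root = result.cost[root] <= result.total + _TOL
    return (int(tmin[root][opt_root].min()), int(tmax[root][opt_root].max()))


def min_max_gains_over_mprs(tree: Tree, matrix: CharacterMatrix,
                            steps: StepMatrix, clade: Clade | None = None,
                            include_stem: bool = True) -> tuple[int, int]:
    """Bracket of ossified-patella origins (gain edges) over all MPRs."""
    return min_max_transitions_over_mprs(
        tree, matrix, steps, GAIN[0], GAIN[1], clade, include_stem)


def ml_transition_bracket(tree: Tree, mapped: dict[Node, frozenset[int]],
                          from_states: frozenset[int] = GAIN[0],
                          to_states: frozenset[int] = GAIN[1],
                          clade: Clade | None = None,
                          include_stem: bool = True) -> tuple[int, int]:
    """Transition-count bracket from a (possibly ambiguous) ML state map.

    An edge contributes to the minimum only when every allowed choice is
    a transition, and to the maximum when some choice is; ambiguous nodes
    therefore widen the bracket rather than being resolved arbitrarily.
    """
    counted = _counted_children(tree, clade, include_stem)
    lo = hi = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        if counted is not None and node not in counted:
            continue
        pset, cset = mapped[node.parent], mapped[node]
        if pset <= from_states and cset <= to_states:
            lo += 1
        if (pset & from_states) and (cset & to_states):
            hi += 1
    return lo, hi


@dataclass
class TransitionSummary:
    """One analysis row: variant x scheme, with per-clade brackets."""

    variant: str
    scheme: str              # "unordered" | "ordered" | "ml"
    score: float             # parsimony cost, or log-likelihood for ML
    per_clade: dict[str, dict[str, int]]

    def flat(self) -> dict[str, float]:
        row: dict[str, float] = {"variant": self.variant,
                                 "scheme": self.scheme, "score": self.score}
        for clade_name in sorted(self.per_clade):
            for key, val in sorted(self.per_clade[clade_name].items()):
                row[f"{clade_name}.{key}"] = val
        return row


def _clade_brackets_parsimony(tree: Tree, matrix: CharacterMatrix,
                              steps: StepMatrix,
                              clades: dict[str, Clade]) -> dict[str, dict[str, int]]:
    per: dict[str, dict[str, int]] = {}
    res = sankoff(tree, matrix, steps)
    for name, clade in clades.items():
        g = min_max_transitions_over_mprs(tree, matrix, steps, *GAIN,
                                          clade=clade, result=res)
        l = min_max_transitions_over_mprs(tree, matrix, steps, *LOSS,
                                          clade=clade, result=res)
        g0 = min_max_transitions_over_mprs(
            tree, matrix, steps, frozenset({0}), frozenset({2}),
            clade=clade, result=res)
        g1 = min_max_transitions_over_mprs(
            tree, matrix, steps, frozenset({1}), frozenset({2}),
            clade=clade, result=res)
        per[name] = {
            "min_gains": g[0], "max_gains": g[1],
            "min_losses": l[0], "max_losses": l[1],
            "min_gains_from0": g0[0], "max_gains_from0": g0[1],
            "min_gains_from1": g1[0], "max_gains_from1": g1[1],
        }
    return per


def scenario_sweep(base_tree: Tree, matrix: CharacterMatrix,
                   variants: dict[str, "object"],
                   clades: dict[str, Clade],
                   schemes: tuple[str, ...] = ("unordered", "ordered"),
                   ml: bool = False,
                   ml_threshold: float = 0.05) -> list[TransitionSummary]:
    """One :class:`TransitionSummary` per (variant x scheme), deterministic.

    ``variants`` maps name -> :class:`~patevol.supertree.TopologyVariant`
    (the identity variant is just an empty rewiring list).  With ``ml``
    the sweep appends a maximum-likelihood row per variant, using the
    fitted symmetric Mk rate and the ambiguity-thresholded state map.
    """
    from .characters import make_step_matrix
    from .mk import fit_rate, map_states, marginal_probs
    from .supertree import apply_variant

    rows: list[TransitionSummary] = []
    for vname in sorted(variants):
        tree = apply_variant(base_tree, variants[vname])
        for scheme in schemes:
            steps = make_step_matrix(scheme, matrix.k)
            res = sankoff(tree, matrix, steps)
            rows.append(TransitionSummary(
                variant=vname, scheme=scheme, score=res.total,
                per_clade=_clade_brackets_parsimony(tree, matrix, steps, clades)))
        if ml:
            fit = fit_rate(tree, matrix)
            mapped = map_states(marginal_probs(tree, matrix, fit.model),
                                threshold=ml_threshold)
            per: dict[str, dict[str, int]] = {}
            for name, clade in clades.items():
                g = ml_transition_bracket(tree, mapped, *GAIN, clade=clade)
                l = ml_transition_bracket(tree, mapped, *LOSS, clade=clade)
                per[name] = {"min_gains": g[0], "max_gains": g[1],
                             "min_losses": l[0], "max_losses": l[1]}
            rows.append(TransitionSummary(
                variant=vname, scheme="ml", score=fit.loglik, per_clade=per))
    return rows


def sweep_table(rows: list[TransitionSummary]) -> pd.DataFrame:
    """Flatten sweep rows into a tidy DataFrame (stable column order)."""
    return pd.DataFrame([r.flat() for r in rows])
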