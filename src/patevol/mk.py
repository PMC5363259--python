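"""Maximum-likelihood ancestral reconstruction under the Mk model.

The headline model is the single-rate symmetric k-state Markov chain
("Mk1"): one instantaneous rate ``q`` (per Myr) between every ordered
state pair and a uniform root prior.  Its transition probabilities have
the closed form::

    p_ij(t) = 1/k (1 - exp(-k q t))              (i != j)
    p_ii(t) = 1/k + (k-1)/k exp(-k q t)

An ordered-rates variant (transitions only between adjacent states of
the absent -> patelloid -> ossified series, with separate gain and loss
rates) is provided for simulation and sensitivity checks; it uses a
numerical matrix exponential.

Likelihoods use Felsenstein pruning with per-node rescaling, so results
do not underflow on deep trees and are independent of the rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .characters import CharacterMatrix, validate_matrix
from .tree import Node, Tree

__all__ = [
    "MkModel", "OrderedRatesModel", "MarginalReconstruction", "RateFit",
    "transition_matrix", "mk_loglik", "fit_rate", "marginal_probs", "map_states",
]


@dataclass(frozen=True)
class MkModel:
    """Symmetric single-rate Mk model with a root prior (default uniform)."""

    q: float
    k: int = 3
    prior: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.q < 0:
            raise ValueError("rate q must be >= 0")
        prior = self.prior
        if prior is None:
            prior = tuple([1.0 / self.k] * self.k)
        prior = tuple(float(p) for p in prior)
        if len(prior) != self.k or abs(sum(prior) - 1.0) > 1e-9:
            raise ValueError("prior must have length k and sum to 1")
        object.__setattr__(self, "prior", prior)

    @property
    def generator(self) -> np.ndarray:
        Q = np.full((self.k, self.k), self.q)
        np.fill_diagonal(Q, -(self.k - 1) * self.q)
        return Q

    def transition(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)


@dataclass(frozen=True)
class OrderedRatesModel:
    """Adjacent-transitions chain 0 <-> 1 <-> 2 with gain/loss rates.

    ``g01, g12`` are gain rates up the series (absent -> patelloid,
    patelloid -> ossified); ``l10, l21`` are loss rates back down.
    Direct 0 <-> 2 jumps have rate zero.
    """

    g01: float
    g12: float
    l10: float
    l21: float
    prior: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    k: int = field(default=3, init=False)

    def __post_init__(self):
        for name in ("g01", "g12", "l10", "l21"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    @property
    def generator(self) -> np.ndarray:
        Q = np.array([
            [-self.g01, self.g01, 0.0],
            [self.l10, -(self.l10 + self.g12), self.g12],
            [0.0, self.l21, -self.l21],
        ])
        return Q

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be >= 0")
        return expm(self.generator * t)


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """Closed-form Mk transition probabilities over ``t`` Myr."""
    if t < 0:
        raise ValueError("time must be >= 0")
    k = model.k
    decay = math.exp(-k * model.q * t)
    off = (1.0 - decay) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, off + decay)
    return P


# ----------------------------------------------------------------------
# pruning

def _tip_partial(states: frozenset[int], k: int) -> np.ndarray:
    vec = np.zeros(k)
    vec[sorted(states)] = 1.0
    return vec


def _partials(tree: Tree, matrix: CharacterMatrix, model) -> tuple[
        dict[Node, np.ndarray], dict[Node, np.ndarray], float]:
    """Inside partials per node, per-edge transition matrices and the
    accumulated log of rescaling factors."""
    k = model.k
    matrix, _ = validate_matrix(matrix, tree)
    P: dict[Node, np.ndarray] = {}
    partial: dict[Node, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder():
        if node is not tree.root:
            P[node] = model.transition(node.branch_length or 0.0)
        if node.is_tip:
            partial[node] = _tip_partial(matrix[node.label], k)
        else:
            vec = np.ones(k)
            for child in node.children:
                vec = vec * (P[child] @ partial[child])
            scale = vec.max()
            if scale > 0:
                vec = vec / scale
                logscale += math.log(scale)
            partial[node] = vec
    return partial, P, logscale


def mk_loglik(tree: Tree, matrix: CharacterMatrix, model) -> float:
    """Log-likelihood of the tip data by Felsenstein pruning.

    Returns ``-inf`` when the data have probability zero (e.g. ``q = 0``
    with conflicting tip states).
    """
    partial, _, logscale = _partials(tree, matrix, model)
    lik = float(np.dot(model.prior, partial[tree.root]))
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


@dataclass
class RateFit:
    """Outcome of maximum-likelihood estimation of the Mk rate."""

    model: MkModel
    loglik: float
    converged: bool
    at_bound: bool
    bounds: tuple[float, float]


def fit_rate(tree: Tree, matrix: CharacterMatrix,
             bounds: tuple[float, float] = (1e-8, 10.0),
             prior: tuple[float, ...] | None = None, k: int = 3) -> RateFit:
    """Fit ``q`` by bounded scalar maximisation of the pruning likelihood.

    With no variation among the tips the likelihood decreases in ``q``
    and the fit lands on the lower bound; this is reported via
    ``at_bound`` rather than raised.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid rate bounds")

    def nll(q: float) -> float:
        ll = mk_loglik(tree, matrix, MkModel(q=q, k=k, prior=prior))
        return -ll if math.isfinite(ll) else 1e300

    # optimise on the log scale: the likelihood varies over orders of
    # magnitude in q and is far better behaved in log q
    res = minimize_scalar(lambda x: nll(math.exp(x)),
                          bounds=(math.log(lo), math.log(hi)),
                          method="bounded", options={"xatol": 1e-12})
    q_hat, ll_hat = float(math.exp(res.x)), -float(res.fun)
    at_bound = False
    # snap to the boundary when it is at least as good as the interior point
    for edge in (lo, hi):
        ll_edge = -nll(edge)
        if ll_edge >= ll_hat - 1e-9:
            q_hat, ll_hat, at_bound = edge, ll_edge, True
    return RateFit(model=MkModel(q=q_hat, k=k, prior=prior), loglik=ll_hat,
                   converged=bool(res.success), at_bound=at_bound,
                   bounds=(lo, hi))


# ----------------------------------------------------------------------
# marginal reconstruction

@dataclass
class MarginalReconstruction:
    """Per-node marginal posterior state probabilities."""

    tree: Tree
    model: object
    node_probs: dict[Node, np.ndarray]
    loglik: float

    def __getitem__(self, node: Node) -> np.ndarray:
        return self.node_probs[node]


def marginal_probs(tree: Tree, matrix: CharacterMatrix, model
                   ) -> MarginalReconstruction:
    """Marginal posterior of every node's state given all tips.

    Standard inside/outside combination: the outside vector of the root
    is the prior; for a child ``c`` of ``v`` it is the prior-weighted
    likelihood of everything outside ``c``'s subtree, propagated through
    the edge matrix.  ``marginal(v) ~ inside(v) * outside(v)``,
    normalised per node (rescaling cancels).
    """
    partial, P, logscale = _partials(tree, matrix, model)
    lik = float(np.dot(model.prior, partial[tree.root]))
    loglik = math.log(lik) + logscale if lik > 0 else -math.inf

    outside: dict[Node, np.ndarray] = {tree.root: np.asarray(model.prior, float)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        messages = [P[c] @ partial[c] for c in node.children]
        for ci, child in enumerate(node.children):
            sib = np.ones(model.k)
            for cj, msg in enumerate(messages):
                if cj != ci:
                    sib = sib * msg
            out = (outside[node] * sib) @ P[child]
            s = out.sum()
            outside[child] = out / s if s > 0 else out

    node_probs: dict[Node, np.ndarray] = {}
    for node in tree.preorder():
        joint = partial[node] * outside[node]
        s = joint.sum()
        if s <= 0:
            raise ValueError(
                "zero-probability data: marginals undefined (q = 0 with "
                "conflicting tip states?)")
        node_probs[node] = joint / s
    return MarginalReconstruction(tree=tree, model=model,
                                  node_probs=node_probs, loglik=loglik)


def map_states(recon: MarginalReconstruction, threshold: float = 0.05
               ) -> dict[Node, frozenset[int]]:
    """Argmax state per node, widened to a set where the call is close.

    Any state whose probability is within ``threshold`` of the node's
    maximum is included, so near-ties surface as ambiguous rather than
    being silently resolved.
    """
    out: dict[Node, frozenset[int]] = {}
    for node, probs in recon.node_probs.items():
        top = probs.max()
        out[node] = frozenset(np.nonzero(probs > top - threshold)[0].tolist())
    return out
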