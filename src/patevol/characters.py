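"""The patellar character: state space, matrices and parsimony costs.

The focal character has three states: 0 = patella absent, 1 = soft-tissue
"patelloid" (fibrocartilaginous), 2 = ossified patella.  ``?`` denotes an
ambiguous coding and is treated everywhere downstream as the full state
set, never silently as one state.  Taxa whose whole hindlimb is lost
(crown Cetacea, crown Sirenia) are coded ``?`` rather than 0: absence of
the limb is inapplicable data, not absence of patellar ossification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import Tree

__all__ = [
    "StateSpace", "PATELLA", "CharacterMatrix", "StepMatrix",
    "make_step_matrix", "validate_matrix", "ValidationReport",
    "read_state_tsv",
]


@dataclass(frozen=True)
class StateSpace:
    """An ordered discrete state space of ``k >= 2`` states."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("need at least 2 states")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be distinct")

    @property
    def k(self) -> int:
        return len(self.labels)


#: The study's three-state patellar character.
PATELLA = StateSpace(("absent", "patelloid/fibrocartilaginous", "ossified"))


class CharacterMatrix:
    """Taxon -> state assignment for one discrete character.

    An assignment is a non-empty frozenset of state indices: a singleton
    for an observed state, the full set for ``?``, and any intermediate
    subset for partial ambiguity.
    """

    def __init__(self, assignments: dict[str, frozenset[int]], k: int = 3):
        self.k = k
        self.assignments: dict[str, frozenset[int]] = {}
        full = frozenset(range(k))
        for taxon, states in assignments.items():
            states = frozenset(states)
            if not states:
                raise ValueError(f"empty state set for taxon {taxon!r}")
            if not states <= full:
                bad = sorted(states - full)
                raise ValueError(
                    f"illegal state(s) {bad} for taxon {taxon!r} (k={k})")
            self.assignments[taxon] = states

    @classmethod
    def from_symbols(cls, symbols: dict[str, str], k: int = 3) -> "CharacterMatrix":
        """Build from one-symbol-per-taxon codes: '0','1','2' or '?'/'-'."""
        full = frozenset(range(k))
        out: dict[str, frozenset[int]] = {}
        for taxon, sym in symbols.items():
            sym = sym.strip()
            if sym in ("?", "-"):
                out[taxon] = full
            elif sym.isdigit() and int(sym) < k:
                out[taxon] = frozenset([int(sym)])
            else:
                raise ValueError(
                    f"illegal state symbol {sym!r} for taxon {taxon!r}")
        return cls(out, k=k)

    def symbol(self, taxon: str) -> str:
        states = self.assignments[taxon]
        if len(states) == self.k:
            return "?"
        if len(states) == 1:
            return str(next(iter(states)))
        return "{" + ",".join(map(str, sorted(states))) + "}"

    def taxa(self) -> list[str]:
        return sorted(self.assignments)

    def __getitem__(self, taxon: str) -> frozenset[int]:
        return self.assignments[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.assignments

    def with_taxon(self, taxon: str, states: frozenset[int]) -> "CharacterMatrix":
        new = dict(self.assignments)
        new[taxon] = frozenset(states)
        return CharacterMatrix(new, k=self.k)


class StepMatrix:
    """A k x k parsimony cost table with zero diagonal."""

    def __init__(self, costs: np.ndarray):
        costs = np.asarray(costs, dtype=float)
        if costs.ndim != 2 or costs.shape[0] != costs.shape[1]:
            raise ValueError("step matrix must be square")
        if np.any(np.diag(costs) != 0):
            raise ValueError("step matrix diagonal must be zero")
        if np.any(costs < 0):
            raise ValueError("step costs must be non-negative")
        self.costs = costs

    @property
    def k(self) -> int:
        return self.costs.shape[0]

    def __call__(self, i: int, j: int) -> float:
        return float(self.costs[i, j])

    def __repr__(self) -> str:  # pragma: no cover
        return f"StepMatrix({self.costs.tolist()})"


def make_step_matrix(mode: str, k: int = 3) -> StepMatrix:
    """Uniform (``unordered``) or linear-series (``ordered``) costs.

    Unordered: every change costs one step, so a direct 0->2 transition is
    a single step.  Ordered: cost ``|i - j|``, so 0->2 must pass through
    the patelloid state and costs two steps.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    idx = np.arange(k)
    if mode == "unordered":
        costs = np.ones((k, k)) - np.eye(k)
    elif mode == "ordered":
        costs = np.abs(idx[:, None] - idx[None, :]).astype(float)
    else:
        raise ValueError(f"unknown step-matrix mode {mode!r}")
    return StepMatrix(costs)


@dataclass
class ValidationReport:
    """Outcome of matching a matrix against a tree's tips."""

    missing_from_matrix: list[str] = field(default_factory=list)  # coded "?"
    missing_from_tree: list[str] = field(default_factory=list)    # ignored
    warnings: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.missing_from_matrix or self.missing_from_tree)


def validate_matrix(matrix: CharacterMatrix, tree: Tree
                    ) -> tuple[CharacterMatrix, ValidationReport]:
    """Reconcile ``matrix`` with ``tree``.

    Tips absent from the matrix are added as ``?`` with a warning; matrix
    taxa absent from the tree are dropped with a warning.  Illegal states
    are impossible by construction of :class:`CharacterMatrix` (hard error
    at build time).  Returns the reconciled matrix and the report.
    """
    report = ValidationReport()
    tips = set(tree.tip_labels())
    full = frozenset(range(matrix.k))
    out: dict[str, frozenset[int]] = {}
    for taxon in sorted(tips):
        if taxon in matrix:
            out[taxon] = matrix[taxon]
        else:
            out[taxon] = full
            report.missing_from_matrix.append(taxon)
            report.warnings.append(
                f"tip {taxon!r} has no coding; treated as '?'")
    for taxon in matrix.taxa():
        if taxon not in tips:
            report.missing_from_tree.append(taxon)
            report.warnings.append(
                f"matrix taxon {taxon!r} not in tree; ignored")
    return CharacterMatrix(out, k=matrix.k), report


def read_state_tsv(text: str, k: int = 3) -> CharacterMatrix:
    """Read a two-column ``taxon<TAB>state`` table (comments start '#')."""
    symbols: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'taxon<TAB>state'")
        symbols[parts[0]] = parts[1]
    return CharacterMatrix.from_symbols(symbols, k=k)
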