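"""Assembly of composite, time-calibrated trees from declarative specs.

The study trees are composites: topology stitched together from several
source phylogenies, with node dates attached where the literature states
them and the remaining internal nodes interpolated so that interbranch
lengths between dated nodes are approximately equal.  This module builds
such trees from a nested :class:`CladeSpec`, fills in undated nodes, and
applies named topology variants (declarative rewirings such as moving
Eomaia onto the therian stem) without duplicating tip codings.

Ages are in Mya with the present at 0; fossil terminals carry their
last-appearance age.  Branch lengths are always re-derived from ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .tree import Clade, Node, Tree, TreeError

__all__ = [
    "CladeSpec", "Rewiring", "TopologyVariant",
    "build_tree", "interpolate_undated_nodes", "apply_variant",
]


@dataclass
class CladeSpec:
    """Nested topology with optional ages (polytomies allowed).

    A node with no children is a terminal; its ``age`` is the terminal
    age (0 for extant taxa, the last-appearance datum for fossils) and
    defaults to 0.  Internal nodes may leave ``age`` unset, to be filled
    by :func:`interpolate_undated_nodes`.
    """

    name: Optional[str] = None
    age: Optional[float] = None
    children: list["CladeSpec"] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "CladeSpec":
        return cls(name=data.get("name"), age=data.get("age"),
                   children=[cls.from_dict(c) for c in data.get("children", [])])

    def to_dict(self) -> dict:
        out: dict = {}
        if self.name is not None:
            out["name"] = self.name
        if self.age is not None:
            out["age"] = self.age
        if self.children:
            out["children"] = [c.to_dict() for c in self.children]
        return out


def build_tree(spec: CladeSpec) -> Tree:
    """Materialise ``spec`` into a dated :class:`Tree`.

    Topology equals the spec (children in spec order, so the output
    Newick is byte-identical for identical specs); every dated node
    carries its age; undated internal nodes are interpolated; branch
    lengths are the age differences.  Raises :class:`TreeError` naming
    both nodes on an age inversion.
    """

    def make(s: CladeSpec, parent_name: Optional[str]) -> Node:
        age = s.age
        if not s.children and age is None:
            age = 0.0
        node = Node(label=s.name, age=age)
        for c in s.children:
            child = make(c, s.name)
            if age is not None and child.age is not None \
                    and child.age > age + 1e-9:
                raise TreeError(
                    f"age inversion: node {s.name!r} ({age} Mya) is younger "
                    f"than its child {c.name!r} ({child.age} Mya)")
            node.add_child(child)
        return node

    root = make(spec, None)
    tree = Tree(root)
    if root.age is None and root.children:
        raise TreeError("root must be dated")
    tree = interpolate_undated_nodes(tree)
    tree.validate()
    return tree


def interpolate_undated_nodes(tree: Tree) -> Tree:
    """Fill in ages of undated internal nodes by even spacing.

    For a chain of ``m`` undated nodes between a dated ancestor (age
    ``a``) and a dated descendant (age ``d``), node ``i`` of the chain
    receives ``a - i * (a - d) / (m + 1)``.  Where an undated node has
    several dated descendants reachable through undated nodes only, the
    oldest evenly-spaced candidate is used, which keeps every path free
    of age inversions.  Requires a dated root and dated tips.
    """
    tree = tree.copy()
    if tree.root.age is None:
        raise TreeError("root must be dated for interpolation")
    for tip in tree.tips():
        if tip.age is None:
            tip.age = 0.0

    def chains(node: Node) -> list[tuple[int, float]]:
        """(undated-count, dated-age) for every nearest dated descendant
        reachable from ``node`` (inclusive) through undated nodes."""
        out: list[tuple[int, float]] = []
        for child in node.children:
            if child.age is not None:
                out.append((1, child.age))
            else:
                out.extend((m + 1, d) for m, d in chains(child))
        return out

    for node in tree.preorder():
        if node.age is not None:
            continue
        parent_age = node.parent.age
        assert parent_age is not None  # preorder guarantees parent done
        candidates = [parent_age - (parent_age - d) / (m + 1)
                      for m, d in chains(node)]
        node.age = max(candidates)

    tree.lengths_from_ages()
    return tree


@dataclass(frozen=True)
class Rewiring:
    """Detach the clade spanned by ``move`` and re-attach it as sister to
    the clade spanned by ``sister_of``, with the new joint node at
    ``age`` Mya."""

    move: tuple[str, ...]
    sister_of: tuple[str, ...]
    age: float


@dataclass(frozen=True)
class TopologyVariant:
    """A named list of rewirings; the empty list is the identity."""

    name: str
    rewirings: tuple[Rewiring, ...] = ()


def apply_variant(tree: Tree, variant: TopologyVariant) -> Tree:
    """Return a new tree with the variant applied; the input is untouched."""
    out = tree.copy()
    for rw in variant.rewirings:
        out = _rewire(out, rw)
    out.validate()
    return out


def _rewire(tree: Tree, rw: Rewiring) -> Tree:
    source = tree.mrca(rw.move)  # raises on dangling labels
    if source is tree.root:
        raise TreeError("cannot detach the root")

    # detach, suppressing a resulting single-child parent
    parent = source.parent
    parent.children.remove(source)
    source.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        grand = parent.parent
        grand.children[grand.children.index(parent)] = only
        only.parent = grand

    target = tree.mrca(rw.sister_of)
    for n in (source, *source.children):
        if target is n:
            raise TreeError("attachment target lies inside the moved clade")
    if target.parent is None:
        raise TreeError("cannot attach as sister of the root")

    joint = Node(age=rw.age)
    tp = target.parent
    tp.children[tp.children.index(target)] = joint
    joint.parent = tp
    joint.add_child(target)
    joint.add_child(source)

    if tp.age is not None and rw.age > tp.age + 1e-9:
        raise TreeError(
            f"age inversion: new node ({rw.age} Mya) older than its parent "
            f"{tp.label!r} ({tp.age} Mya)")
    for child in joint.children:
        if child.age is not None and child.age > rw.age + 1e-9:
            raise TreeError(
                f"age inversion: new node ({rw.age} Mya) younger than child "
                f"{child.label!r} ({child.age} Mya)")

    tree.lengths_from_ages()
    return tree
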