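"""Rooted phylogenetic trees with branch lengths in millions of years.

The tree type used throughout the package is deliberately small: a rooted
tree whose nodes may carry a label, a branch length (Myr, on non-root
nodes) and optionally an absolute age (Mya, present = 0).  Polytomies are
first-class: every algorithm in this package iterates over ``children``
rather than assuming a binary split, because the composite mammal trees
contain hard polytomies (e.g. Juramaia + Eomaia + crown Placentalia).

When node ages are set they are the single source of truth: branch lengths
are re-derived as ``parent_age - child_age``.  Zero-length branches are
legal (identical dates) and no algorithm divides by a branch length.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Optional

__all__ = ["Node", "Tree", "Clade", "TreeError"]

AGE_TOL = 1e-6


class TreeError(ValueError):
    """Raised for structurally invalid trees or unknown labels."""


class Node:
    """A node in a rooted tree.

    Attributes
    ----------
    label : str or None
        Tip labels are required and unique; internal labels are optional.
    children : list of Node
    parent : Node or None
        ``None`` exactly for the root.
    branch_length : float or None
        Length of the edge to the parent, in Myr.  ``None`` on the root.
    age : float or None
        Absolute age in Mya (present = 0), if dated.
    """

    __slots__ = ("label", "children", "parent", "branch_length", "age")

    def __init__(self, label: Optional[str] = None,
                 branch_length: Optional[float] = None,
                 age: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.branch_length = branch_length
        self.age = age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal[{len(self.children)}]"
        return f"<Node {self.label!r} {kind} bl={self.branch_length} age={self.age}>"


class Clade:
    """A named set of tip labels delimiting a subtree of interest."""

    def __init__(self, name: str, members: Iterable[str]):
        self.name = name
        self.members = frozenset(members)
        if not self.members:
            raise ValueError(f"clade {name!r} has no members")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Clade({self.name!r}, {sorted(self.members)!r})"


class Tree:
    """A rooted tree.  See module docstring for conventions."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversals

    def postorder(self) -> Iterator[Node]:
        """Yield nodes children-before-parents (iterative, stack-safe)."""
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        """Yield nodes parents-before-children."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for n in self.preorder():
            if n.label == label:
                return n
        raise TreeError(f"no node labelled {label!r} in tree")

    # ------------------------------------------------------------------
    # queries

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip (or node) labels.

        Raises :class:`TreeError` naming the first unknown label.
        """
        labels = list(labels)
        wanted = set(labels)
        found: dict[str, Node] = {}
        for n in self.preorder():
            if n.label in wanted:
                found[n.label] = n
        for lab in labels:
            if lab not in found:
                raise TreeError(f"unknown label {lab!r}")
        paths = []
        for lab in labels:
            path = []
            n: Optional[Node] = found[lab]
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(path[::-1])  # root ... node
        # deepest node common to all root-to-node paths
        mrca = self.root
        for depth in range(min(len(p) for p in paths)):
            candidate = paths[0][depth]
            if all(p[depth] is candidate for p in paths):
                mrca = candidate
            else:
                break
        return mrca

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`TreeError` if broken."""
        seen: set[int] = set()
        tip_labels: list[str] = []
        for node in self.preorder():
            if id(node) in seen:
                raise TreeError("tree contains a cycle or shared node")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise TreeError(f"broken parent link at {child.label!r}")
            if node is not self.root:
                if node.branch_length is None or node.branch_length < 0:
                    raise TreeError(
                        f"non-root node {node.label!r} has invalid branch length "
                        f"{node.branch_length!r}")
            if node.age is not None and node.parent is not None \
                    and node.parent.age is not None:
                if node.parent.age < node.age - AGE_TOL:
                    raise TreeError(
                        f"age inversion: {node.parent.label!r} "
                        f"({node.parent.age}) younger than {node.label!r} ({node.age})")
                if node.branch_length is not None and abs(
                        (node.parent.age - node.age) - node.branch_length) > AGE_TOL:
                    raise TreeError(
                        f"branch length of {node.label!r} disagrees with ages")
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip without a label")
                tip_labels.append(node.label)
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------------
    # editing / derived trees

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.branch_length, node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new
        return Tree(clone(self.root))

    def lengths_from_ages(self) -> None:
        """Re-derive every branch length from node ages (ages must be set)."""
        for node in self.preorder():
            if node.parent is not None:
                if node.age is None or node.parent.age is None:
                    raise TreeError(
                        f"cannot derive length at {node.label!r}: missing age")
                node.branch_length = node.parent.age - node.age
                if node.branch_length < -AGE_TOL:
                    raise TreeError(
                        f"age inversion: {node.parent.label!r} younger than "
                        f"{node.label!r}")
                node.branch_length = max(node.branch_length, 0.0)

    def extract_subtree(self, clade: Clade) -> "Tree":
        """Subtree rooted at the MRCA of ``clade.members``, pruned to members.

        Non-member tips inside the MRCA's subtree are pruned; internal nodes
        left with a single child are suppressed (their branch lengths summed)
        so the result contains exactly the members and their connecting
        nodes.  Branch lengths along retained paths are preserved.
        """
        missing = clade.members - set(self.tip_labels())
        if missing:
            raise TreeError(
                f"clade {clade.name!r} members not in tree: {sorted(missing)}")
        anchor = self.mrca(clade.members)

        def build(node: Node) -> Optional[Node]:
            if node.is_tip:
                if node.label in clade.members:
                    return Node(node.label, node.branch_length, node.age)
                return None
            kept = [b for b in (build(c) for c in node.children) if b is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # suppress the pass-through node, absorbing its edge
                child = kept[0]
                if node.branch_length is not None and child.branch_length is not None:
                    child.branch_length += node.branch_length
                elif node.branch_length is not None:
                    child.branch_length = node.branch_length
                return child
            new = Node(node.label, node.branch_length, node.age)
            for k in kept:
                new.add_child(k)
            return new

        sub_root = build(anchor)
        assert sub_root is not None
        sub_root.branch_length = None
        sub_root.parent = None
        return Tree(sub_root)

    # ------------------------------------------------------------------
    # comparisons

    def splits(self) -> set[frozenset[str]]:
        """Tip-label sets of every internal edge (plus trivial tip splits)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
            if node is not self.root:
                out.add(below[id(node)])
        return out

    def same_topology(self, other: "Tree") -> bool:
        return (set(self.tip_labels()) == set(other.tip_labels())
                and self.splits() == other.splits())

    def depth(self, node: Node) -> float:
        """Sum of branch lengths from the root down to ``node``."""
        d = 0.0
        while node.parent is not None:
            d += node.branch_length or 0.0
            node = node.parent
        return d

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())
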