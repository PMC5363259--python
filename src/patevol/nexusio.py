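"""Nexus and Newick reading/writing.

Reading is delegated to :mod:`dendropy`, which copes with the Mesquite
Nexus dialect (``TITLE``/``LINK`` lines inside blocks, square-bracket
comments, case-insensitive keywords).  Writing is done by hand so that a
given document always serialises to byte-identical output: taxa are
written alphabetically, trees in insertion order, and numbers in a fixed
format.

Trees are treated as rooted as written (``[&R]`` honoured; unflagged
trees are read as rooted too, because ancestral reconstruction is
direction-dependent).  Character symbols are restricted to ``0 1 2`` with
``?`` and ``-`` both read as missing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

from .tree import Node, Tree

__all__ = [
    "NexusDocument", "NexusError",
    "read_nexus", "write_nexus", "read_newick", "write_newick",
]

ALLOWED_SYMBOLS = {"0", "1", "2"}
MISSING_SYMBOLS = {"?", "-"}


class NexusError(ValueError):
    """Malformed Nexus/Newick input (carries position info when known)."""


@dataclass
class NexusDocument:
    """In-memory Nexus file: taxa, an optional standard-character matrix
    (taxon -> symbol string, one symbol per character) and named rooted
    trees in insertion order."""

    taxa: list[str] = field(default_factory=list)
    characters: dict[str, str] = field(default_factory=dict)
    trees: list[tuple[str, Tree]] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NexusDocument):
            return NotImplemented
        return (sorted(self.taxa) == sorted(other.taxa)
                and self.characters == other.characters
                and [name for name, _ in self.trees]
                    == [name for name, _ in other.trees]
                and all(write_newick(a) == write_newick(b)
                        for (_, a), (_, b) in zip(self.trees, other.trees)))


# ----------------------------------------------------------------------
# dendropy <-> patevol conversion

def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, branch_length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _tree_from_dendropy(dtree: dendropy.Tree) -> Tree:
    root = _from_dendropy(dtree.seed_node)
    root.branch_length = None
    tree = Tree(root)
    tree.validate()
    return tree


# ----------------------------------------------------------------------
# reading

def read_nexus(text: str) -> NexusDocument:
    """Parse Nexus ``text`` into a :class:`NexusDocument`.

    Raises :class:`NexusError` with a line number for malformed blocks and
    names the offending taxon and symbol for illegal character states.
    """
    ds = dendropy.DataSet()
    try:
        ds.read(data=text, schema="nexus", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:  # pragma: no cover - msg path
        line = getattr(exc, "line_num", None)
        raise NexusError(f"malformed Nexus (line {line}): {exc}") from exc
    except Exception as exc:
        raise NexusError(f"malformed Nexus: {exc}") from exc

    doc = NexusDocument()
    seen: set[str] = set()
    for tns in ds.taxon_namespaces:
        for taxon in tns:
            if taxon.label not in seen:
                seen.add(taxon.label)
                doc.taxa.append(taxon.label)

    for cm in ds.char_matrices:
        for taxon in cm:
            symbols = []
            for cell in cm[taxon]:
                sym = str(cell)
                if sym in MISSING_SYMBOLS:
                    sym = "?"
                elif sym not in ALLOWED_SYMBOLS:
                    raise NexusError(
                        f"illegal state symbol {sym!r} for taxon {taxon.label!r}")
                symbols.append(sym)
            doc.characters[taxon.label] = "".join(symbols)

    for tl in ds.tree_lists:
        for dtree in tl:
            name = dtree.label or f"tree_{len(doc.trees) + 1}"
            doc.trees.append((name, _tree_from_dendropy(dtree)))
    return doc


def read_newick(text: str) -> Tree:
    """Parse a single Newick string into a rooted :class:`Tree`.

    Polytomies are preserved, never resolved.  Unbalanced parentheses and
    other syntax errors raise :class:`NexusError` with position info.
    """
    stripped = text.strip()
    if stripped.count("(") != stripped.count(")"):
        raise NexusError(
            f"unbalanced parentheses in Newick (open={stripped.count('(')}, "
            f"close={stripped.count(')')})")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:
        raise NexusError(f"Newick parse error: {exc}") from exc
    return _tree_from_dendropy(dtree)


# ----------------------------------------------------------------------
# writing

def _fmt_length(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(round(float(x), 10))


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _fmt_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    """Serialise ``tree`` to Newick; deterministic for a given tree."""
    out = io.StringIO()

    def walk(node: Node) -> None:
        if node.children:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                walk(child)
            out.write(")")
        if node.label:
            out.write(_fmt_label(node.label))
        if include_lengths and node.branch_length is not None:
            out.write(":" + _fmt_length(node.branch_length))

    walk(tree.root)
    out.write(";")
    return out.getvalue()


def write_nexus(doc: NexusDocument) -> str:
    """Serialise ``doc``; output re-parses to an equal document.

    Taxa are written alphabetically; empty blocks are omitted entirely.
    """
    lines = ["#NEXUS", ""]
    taxa = sorted(set(doc.taxa) | set(doc.characters))
    if taxa:
        lines += ["BEGIN TAXA;",
                  f"    DIMENSIONS NTAX={len(taxa)};",
                  "    TAXLABELS",
                  *(f"        {_fmt_label(t)}" for t in taxa),
                  "    ;",
                  "END;", ""]
    if doc.characters:
        nchar = len(next(iter(doc.characters.values())))
        for taxon, states in doc.characters.items():
            if len(states) != nchar:
                raise NexusError(
                    f"taxon {taxon!r} has {len(states)} characters, expected {nchar}")
        width = max(len(_fmt_label(t)) for t in doc.characters)
        lines += ["BEGIN CHARACTERS;",
                  f"    DIMENSIONS NCHAR={nchar};",
                  "    FORMAT DATATYPE=STANDARD SYMBOLS=\"012\" MISSING=? GAP=-;",
                  "    MATRIX"]
        for taxon in sorted(doc.characters):
            lines.append(f"        {_fmt_label(taxon):<{width}}  "
                         f"{doc.characters[taxon]}")
        lines += ["    ;", "END;", ""]
    if doc.trees:
        lines.append("BEGIN TREES;")
        for name, tree in doc.trees:
            lines.append(
                f"    TREE {_fmt_label(name)} = [&R] {write_newick(tree)}")
        lines += ["END;", ""]
    return "\n".join(lines)
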