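"""Rooted phylogenies with polytomies, plus Newick I/O.

The reference trees onto which stem characters are mapped are taken as given
(typically built from rRNA data by external software): they are read from
Newick, kept rooted exactly as written, and polytomies are preserved rather
than arbitrarily resolved, because the parsimony machinery downstream handles
multifurcating nodes directly. Nodes carry a stable post-order id; unnamed
internal nodes are labeled ``N<id>`` for exports.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

from .errors import FormatError, ValidationError


class Node:
    """One tree node; ``children`` empty for leaves."""

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves()}

    def __repr__(self):
        return f"Node({self.name!r}, id={self.id}, n_children={len(self.children)})"


class PhyloTree:
    """A rooted tree with named leaves; polytomies allowed."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        names = [n.name for n in self.root.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf names: {dupes}")
        for i, node in enumerate(self.root.postorder()):
            node.id = i
            if not node.is_leaf and not node.name:
                node.name = f"N{i}"

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise ValidationError(f"duplicate leaf names: {exc}") from exc
            raise FormatError(f"Newick parse error: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                name = None
            node = Node(name=name, length=dnode.edge.length)
            if not dnode.is_leaf() and dnode.label:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.name = dnode.label
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return list(self.root.postorder())

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def node(self, node_id: int) -> Node:
        for n in self.root.postorder():
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(names)
        missing = want - set(self.leaf_names)
        if missing:
            raise ValidationError(f"leaves not in tree: {sorted(missing)}")
        for node in self.root.postorder():
            if want <= node.leaf_names():
                return node
        return self.root

    # -- transforms --------------------------------------------------------

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Tree restricted to the named leaves; unary nodes are spliced out
        (child branch lengths summed), matching standard pruning semantics."""
        keep = set(keep)
        missing = keep - set(self.leaf_names)
        if missing:
            raise ValidationError(f"leaves not in tree: {sorted(missing)}")
        if not keep:
            raise ValidationError("cannot prune to an empty leaf set")

        def rebuild(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in keep:
                    return Node(node.name, node.length, node.support)
                return None
            kept = [rebuild(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                only = kept[0]
                if only.length is not None or node.length is not None:
                    only.length = (only.length or 0.0) + (node.length or 0.0)
                return only
            new = Node(None, node.length, node.support)
            for c in kept:
                new.add(c)
            return new

        new_root = rebuild(self.root)
        new_root.length = None
        return PhyloTree(new_root)

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    # -- serialization -----------------------------------------------------

    def to_newick(self, include_internal_names: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.name)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_internal_names and node.name:
                    s += _quote(node.name)
                elif node.support is not None:
                    s += f"{node.support:g}"
            if node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree, preserving polytomies."""
    return PhyloTree.read(path)


def _quote(name: str) -> str:
    if name is None:
        return ""
    if any(ch in name for ch in "()[]{}:;, '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name
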