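"""Rooted phylogenetic trees with branch lengths and node supports.

The container is deliberately small: a mutable node structure that the
likelihood engine, the parsimony search, and the rate calculations all walk
directly. Newick parsing is delegated to dendropy; only the serializer is
local (the dialect written is plain Newick with internal-node support labels,
the same dialect the reader accepts).
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import dendropy

from .errors import TreeParseError, ValidationError

__all__ = ["Node", "PhyloTree"]


class Node:
    """A tree node. ``length`` is the length of the edge above the node."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name: Optional[str] = name
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        dup = Node(self.name, self.length, self.support)
        for c in self.children:
            dup.add_child(c.copy())
        return dup


class PhyloTree:
    """Rooted tree with unique tip names, non-negative branch lengths and
    optional support values in [0, 1] on internal nodes."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # ---------------------------------------------------------------- basic
    def validate(self) -> None:
        names = self.tip_names
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate tip names: {dup}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at {node.name!r}"
                )
            if node.is_leaf and node.support is not None:
                raise ValidationError("support value on a tip")
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise ValidationError(f"support {node.support} outside [0, 1]")

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.root.leaves())

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.root.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), validate=False)

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.root.postorder() if n is not self.root
        )

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2
            for n in self.root.postorder()
            if not n.is_leaf
        )

    def total_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.root.postorder() if n is not self.root
        )

    def scale_branch_lengths(self, factor: float) -> None:
        for n in self.root.postorder():
            if n is not self.root and n.length is not None:
                n.length *= factor

    # ------------------------------------------------------------ structure
    def mrca(self, names: Sequence[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(names)
        found = {}
        for node in self.root.postorder():
            if node.is_leaf:
                found[node] = {node.name} & want
            else:
                found[node] = set().union(*(found[c] for c in node.children))
            if found[node] == want:
                return node
        missing = want - set(self.tip_names)
        raise ValidationError(f"tips not in tree: {sorted(missing)}")

    def descendant_tip_names(self, node: Node) -> set[str]:
        return {n.name for n in node.postorder() if n.is_leaf}

    def suppress_unifurcations(self) -> None:
        """Remove degree-2 nodes, summing the lengths of merged edges."""
        changed = True
        while changed:
            changed = False
            for node in list(self.root.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                if node.parent is None:
                    child.parent = None
                    self.root = child
                else:
                    idx = node.parent.children.index(node)
                    node.parent.children[idx] = child
                    child.parent = node.parent
                changed = True

    def splits(self) -> frozenset[frozenset[str]]:
        """Unrooted non-trivial splits, as frozensets of tip names on the
        smaller (canonical) side. Used to compare topologies."""
        all_tips = frozenset(self.tip_names)
        out = set()
        for node in self.root.postorder():
            if node.is_leaf or node is self.root:
                continue
            below = frozenset(self.descendant_tip_names(node))
            above = all_tips - below
            if len(below) < 2 or len(above) < 2:
                continue
            out.add(min(below, above, key=lambda s: (len(s), sorted(s))))
        return frozenset(out)

    # ----------------------------------------------------------------- I/O
    def to_newick(self, include_supports: bool = True,
                  support_as_percent: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_supports and node.support is not None:
                    v = node.support * 100 if support_as_percent else node.support
                    s += f"{v:g}"
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, percent_supports: bool = True) -> "PhyloTree":
        """Parse a Newick string; numeric internal-node labels become support
        values (values > 1 divided by 100 when ``percent_supports``)."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                terminating_semicolon_required=False,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeParseError(f"could not parse Newick: {exc}") from exc
        return cls(_from_dendropy(dtree.seed_node, percent_supports))


def _from_dendropy(dnode, percent_supports: bool) -> Node:
    name = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = Node(length=dnode.edge.length)
    if dnode.is_leaf():
        node.name = name
    else:
        support = _numeric_or_none(name)
        if support is not None:
            if support > 1.0:
                if not percent_supports:
                    raise ValidationError(
                        f"support {support} > 1 but percent dialect disabled"
                    )
                support /= 100.0
            node.support = support
        else:
            node.name = name
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child, percent_supports))
    return node


def _numeric_or_none(label) -> Optional[float]:
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None
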