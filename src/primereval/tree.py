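"""Phylogenetic tree structure shared by all analysis modules.

Trees are stored rooted (an unrooted binary tree appears as a root of
degree 3) with branch lengths on every non-root node and optional
bootstrap supports, as fractions in [0, 1], on internal nodes.
Newick parsing and serialization are delegated to dendropy; both common
support conventions (numeric internal-node labels and bracketed branch
comments) are understood.
"""

from __future__ import annotations

import io as _io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Clade", "PhyloTree"]


class Clade:
    """A node; ``length`` is the length of the edge above it."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
        children: Optional[list["Clade"]] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Clade] = children or []
        self.parent: Optional[Clade] = None
        for c in self.children:
            c.parent = self

    def add(self, child: "Clade") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Clade {self.name or ''} {kind} len={self.length:g}>"


class PhyloTree:
    """An (un)rooted tree with branch lengths and optional supports."""

    def __init__(self, root: Clade):
        self.root = root
        root.parent = None
        root.length = 0.0

    # ------------------------------------------------------------- traversal
    def preorder(self) -> Iterator[Clade]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Clade]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Clade]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Clade]:
        return [n for n in self.preorder() if not n.is_leaf]

    def n_edges(self) -> int:
        return sum(1 for n in self.preorder() if n.parent is not None)

    def copy(self) -> "PhyloTree":
        def rec(node: Clade) -> Clade:
            return Clade(node.name, node.length, node.support,
                         [rec(c) for c in node.children])

        return PhyloTree(rec(self.root))

    # ----------------------------------------------------------- validation
    def validate(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels in tree")
        for node in self.preorder():
            if node.parent is not None and node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} on {node.name!r}")
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise ValueError(f"support {node.support} outside [0, 1]")

    def deroot(self) -> "PhyloTree":
        """Collapse a degree-2 root so the tree reads as unrooted."""
        root = self.root
        while len(root.children) == 2 and not root.is_leaf:
            a, b = root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree: nothing to collapse further
                break
            fold.length += keep.length
            if fold.support is None:
                fold.support = keep.support
            root.children = list(keep.children)
            for c in root.children:
                c.parent = root
            root.children.append(fold)
            fold.parent = root
            root = self.root
        return self

    # -------------------------------------------------------------- newick
    @classmethod
    def from_newick(
        cls,
        text: str,
        support_dialect: str = "auto",
    ) -> "PhyloTree":
        """Parse a Newick string.

        support_dialect: "auto" (numeric internal-node labels become
        supports), "internal-node-label", "branch-comment", or "none".
        Supports on a 0-100 scale (any value > 1) are rescaled to [0, 1].
        """
        if support_dialect not in {"auto", "internal-node-label",
                                   "branch-comment", "none"}:
            raise ValueError(f"unknown support dialect {support_dialect!r}")
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=False,
            )
        except Exception as exc:
            raise ValueError(f"Newick parse error: {exc}") from exc

        def support_of(dnode) -> Optional[float]:
            if support_dialect in {"auto", "internal-node-label"}:
                if dnode.label is not None:
                    try:
                        return float(dnode.label)
                    except ValueError:
                        if support_dialect == "internal-node-label":
                            raise ValueError(
                                f"non-numeric support label {dnode.label!r}")
                        return None
            if support_dialect in {"auto", "branch-comment"}:
                for comment in (dnode.comments or []):
                    try:
                        return float(comment)
                    except ValueError:
                        continue
            return None

        def rec(dnode) -> Clade:
            length = dnode.edge.length
            if length is not None and length < 0:
                raise ValueError(f"negative branch length {length}")
            children = [rec(c) for c in dnode.child_nodes()]
            if children:
                name = None
                support = support_of(dnode)
            else:
                name = dnode.taxon.label if dnode.taxon else dnode.label
                support = None
            return Clade(name=name, length=float(length or 0.0),
                         support=support, children=children)

        tree = cls(rec(dtree.seed_node))
        tree.root.support = None  # root has no edge
        supports = [n.support for n in tree.preorder() if n.support is not None]
        if supports and max(supports) > 1.0:
            for n in tree.preorder():
                if n.support is not None:
                    n.support = n.support / 100.0
        tree.validate()
        return tree

    def to_newick(self, support_dialect: str = "internal-node-label",
                  precision: int = 10) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.name}:{fmt(node.length)}"
            inner = ",".join(rec(c) for c in node.children)
            label = ""
            if node.support is not None:
                if support_dialect == "internal-node-label":
                    label = fmt(node.support)
                elif support_dialect == "branch-comment":
                    label = f"[{fmt(node.support)}]"
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{fmt(node.length)}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={len(self.leaves())}>"

    # --------------------------------------------------------------- edits
    def map_supports(self, fn: Callable[[Optional[float]], Optional[float]]):
        for node in self.preorder():
            if not node.is_leaf and node.parent is not None:
                node.support = fn(node.support)
        return self


def _roundtrip_check(tree: PhyloTree) -> PhyloTree:  # pragma: no cover
    return PhyloTree.from_newick(tree.to_newick())
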