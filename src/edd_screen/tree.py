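"""Lightweight unrooted phylogenetic trees.

Trees are stored as a rooted node structure; the root is an arbitrary
(typically trifurcating) node and carries no branch length.  All tree
statistics exposed here (bipartitions, monophyly, parsimony) are invariant
to the choice of root.
"""

from __future__ import annotations

from typing import Iterator

from .errors import TreeSizeError

__all__ = ["TreeNode", "PhyloTree"]


class TreeNode:
    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
        children: list["TreeNode"] | None = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode(name={self.name!r}, length={self.length!r}, k={len(self.children)})"


class PhyloTree:
    """Unrooted tree with branch lengths and optional internal supports."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- basic accessors ------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaf_names())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def n_edges(self) -> int:
        # every node except the root sits below exactly one edge
        return sum(1 for _ in self.root.postorder()) - 1

    # -- bipartitions ---------------------------------------------------

    def clades(self) -> list[frozenset[str]]:
        """Leaf set under every non-root node (one entry per edge)."""
        out: list[frozenset[str]] = []
        sets: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.name])
            else:
                sets[id(node)] = frozenset().union(
                    *(sets[id(c)] for c in node.children)
                )
            if node is not self.root:
                out.append(sets[id(node)])
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalised.

        Each internal edge splits the leaves into two sets; the side *not*
        containing the lexicographically smallest leaf represents the split,
        so bipartition sets are directly comparable between trees on the
        same leaf set.
        """
        all_leaves = frozenset(self.root.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for clade in self.clades():
            if len(clade) < 2 or len(all_leaves - clade) < 2:
                continue  # trivial (pendant) edge
            side = clade if anchor not in clade else all_leaves - clade
            out.add(side)
        return out

    def require_min_leaves(self, n: int, what: str = "operation") -> None:
        if self.n_leaves < n:
            raise TreeSizeError(f"{what} requires at least {n} leaves")
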