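"""Light-weight rooted tree for gain/loss parsimony.

Nodes carry parent pointers; each non-root node identifies the edge above it,
and the edge above the root is the "stem" edge (named after the root).
Unnamed internal nodes receive deterministic names from their post-order
index so that scenario edge sets are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class RootedTree:
    """A rooted, leaf-labeled tree with unique node names."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_names()
        names = [n.name for n in self.postorder()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")

    def _assign_names(self) -> None:
        # deterministic post-order naming of unnamed internal nodes
        for idx, node in enumerate(self.postorder()):
            if not node.name:
                node.name = f"node{idx}"

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def node(self, name: str) -> TreeNode:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def mrca(self, names: set[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves."""
        if not names:
            raise ValueError("mrca of empty set")
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.name} & names
            else:
                below[id(n)] = set().union(*(below[id(c)] for c in n.children))
        missing = names - below[id(self.root)]
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        for n in self.postorder():
            if below[id(n)] == names:
                return n
        return self.root

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.name}"

        return fmt(self.root) + ";"

    def __len__(self) -> int:
        return sum(1 for _ in self.postorder())
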